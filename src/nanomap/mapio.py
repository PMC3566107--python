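"""Readers and writers for the on-disk formats and the run configuration.

Simplified text dialects of the public molecule/map/alignment formats (column
subsets, flagged with a ``# nanomap-dialect=1`` header). All writers use
stable ordering and fixed float formatting so identical runs produce
byte-identical files. Positions are 1-based on disk and 0-based in memory;
the +/-1 shift is applied exactly once, at this boundary.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._defaults import load_defaults
from .asmcheck import AsmParams, CompletenessReport, Discrepancy
from .consensus import ConsensusMap, ConsensusParams, Peak
from .errors import FormatError, ValidationError
from .mapalign import AlignParams, MapAlignment
from .molsim import MoleculeMap, SimulationParams
from .motifmap import ChannelSpec, ReferenceMap

DIALECT_HEADER = "# nanomap-dialect=1"


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------- BNX

def write_bnx(molecules: list[MoleculeMap], path, header_extra: dict | None = None) -> None:
    """Molecule maps: '0' line per molecule, one channel-prefixed line per color."""
    with open(path, "w") as fh:
        fh.write(DIALECT_HEADER + "\n")
        fh.write("# format=bnx-like\n")
        for k in sorted((header_extra or {})):
            fh.write(f"# {k}={header_extra[k]}\n")
        for mol in molecules:
            fh.write(f"0\t{mol.molecule_id}\t{mol.length_bp:.1f}\n")
            for ch in sorted(mol.labels):
                pos = "\t".join(f"{p:.1f}" for p in mol.labels[ch])
                fh.write(f"{ch}" + ("\t" + pos if len(mol.labels[ch]) else "") + "\n")


def read_bnx(path) -> list[MoleculeMap]:
    molecules: list[MoleculeMap] = []
    current: MoleculeMap | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "0":
                if len(parts) != 3:
                    raise FormatError("malformed molecule line", str(path), ln)
                try:
                    length = float(parts[2])
                except ValueError:
                    raise FormatError("bad molecule length", str(path), ln)
                current = MoleculeMap(parts[1], length, {})
                molecules.append(current)
            else:
                if current is None:
                    raise FormatError("label line before any molecule line", str(path), ln)
                try:
                    ch = int(parts[0])
                    pos = np.asarray([float(x) for x in parts[1:]])
                except ValueError:
                    raise FormatError("bad label line", str(path), ln)
                if len(pos) and (pos.min() < 0 or pos.max() > current.length_bp + 0.05):
                    raise ValidationError(
                        f"{current.molecule_id}: position outside [0, length] at line {ln}"
                    )
                current.labels[ch] = pos
    return molecules


def write_truth_tsv(molecules: list[MoleculeMap], path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tchannel\tposition_bp\tprovenance\torientation\tsource_id\n")
        for mol in molecules:
            if mol.truth is None:
                continue
            for ch in sorted(mol.labels):
                tags = mol.truth.provenance.get(ch, [""] * len(mol.labels[ch]))
                for p, tag in zip(mol.labels[ch], tags):
                    fh.write(
                        f"{mol.molecule_id}\t{ch}\t{p:.1f}\t{tag or 'false'}"
                        f"\t{mol.truth.orientation}\t{mol.truth.source_id}\n"
                    )


# ---------------------------------------------------------------- CMAP

_CMAP_COLS = ["CMapId", "ContigLength", "NumSites", "SiteID",
              "LabelChannel", "Position", "StdDev", "Coverage"]


def _map_rows(m) -> list[tuple[int, float, float, int]]:
    """(channel, position, sd, coverage) rows sorted by (position, channel)."""
    rows = []
    if hasattr(m, "peaks"):
        for ch, pks in m.peaks.items():
            rows.extend((ch, p.position_bp, p.sd_bp, p.support) for p in pks)
    else:
        for ch, pos in m.labels.items():
            rows.extend((ch, float(p), 0.0, 0) for p in pos)
    rows.sort(key=lambda r: (r[1], r[0]))
    return rows


def write_cmap(maps, path, header_extra: dict | None = None) -> None:
    if not isinstance(maps, (list, tuple)):
        maps = [maps]
    with open(path, "w") as fh:
        fh.write(DIALECT_HEADER + "\n")
        fh.write("# format=cmap-like\n")
        for k in sorted((header_extra or {})):
            fh.write(f"# {k}={header_extra[k]}\n")
        for m in maps:
            if hasattr(m, "n_molecules"):
                fh.write(f"# n_molecules {m.map_id}={m.n_molecules}\n")
        fh.write("#h " + "\t".join(_CMAP_COLS) + "\n")
        for m in maps:
            rows = _map_rows(m)
            for sid, (ch, pos, sd, cov) in enumerate(rows, start=1):
                fh.write(
                    f"{m.map_id}\t{float(m.length_bp):.1f}\t{len(rows)}\t{sid}"
                    f"\t{ch}\t{pos + 1.0:.1f}\t{sd:.1f}\t{cov}\n"
                )


def read_cmap(path, kind: str = "auto"):
    """Parse a CMAP-style file into ReferenceMap or ConsensusMap objects.

    kind='auto' returns ReferenceMaps when every StdDev and Coverage is zero,
    otherwise ConsensusMaps; 'reference'/'consensus' force the type.
    """
    per_map: dict[str, dict] = {}
    n_mol: dict[str, int] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# n_molecules "):
                    body = line[len("# n_molecules "):]
                    mid, _, val = body.partition("=")
                    n_mol[mid] = int(val)
                continue
            parts = line.split("\t")
            if len(parts) != len(_CMAP_COLS):
                raise FormatError("wrong column count", str(path), ln)
            mid = parts[0]
            try:
                length = float(parts[1])
                sid = int(parts[3])
                ch = int(parts[4])
                pos = float(parts[5]) - 1.0
                sd = float(parts[6])
                cov = int(parts[7])
            except ValueError:
                raise FormatError("bad field", str(path), ln)
            entry = per_map.setdefault(mid, {"length": length, "rows": [], "sids": set()})
            if sid in entry["sids"]:
                raise FormatError(f"duplicate SiteID {sid} in map {mid}", str(path), ln)
            entry["sids"].add(sid)
            if entry["rows"] and pos < entry["rows"][-1][1]:
                raise FormatError("non-monotone positions", str(path), ln)
            entry["rows"].append((ch, pos, sd, cov))
            if mid not in order:
                order.append(mid)

    out = []
    for mid in order:
        entry = per_map[mid]
        rows = entry["rows"]
        insilico = all(sd == 0.0 and cov == 0 for _, _, sd, cov in rows)
        as_ref = kind == "reference" or (kind == "auto" and insilico)
        if as_ref:
            labels: dict[int, list[int]] = {}
            for ch, pos, _, _ in rows:
                labels.setdefault(ch, []).append(int(round(pos)))
            out.append(ReferenceMap(mid, int(round(entry["length"])), labels))
        else:
            peaks: dict[int, list[Peak]] = {}
            max_cov = 1
            for ch, pos, sd, cov in rows:
                peaks.setdefault(ch, []).append(Peak(pos, sd, max(cov, 1)))
                max_cov = max(max_cov, cov)
            cm = ConsensusMap(mid, entry["length"], peaks, n_mol.get(mid, max_cov))
            cm.validate()
            out.append(cm)
    return out


# ---------------------------------------------------------------- XMAP

_XMAP_COLS = ["XmapEntryID", "QryContigID", "RefContigID", "QryStartPos", "QryEndPos",
              "RefStartPos", "RefEndPos", "Orientation", "Confidence", "Alignment"]


def write_xmap(alignments, path) -> None:
    if not isinstance(alignments, (list, tuple)):
        alignments = [alignments]
    with open(path, "w") as fh:
        fh.write(DIALECT_HEADER + "\n")
        fh.write("# format=xmap-like\n")
        fh.write("#h " + "\t".join(_XMAP_COLS) + "\n")
        for eid, aln in enumerate(alignments, start=1):
            if not aln.matches:
                continue
            qpos = [q for _, q, _ in aln.match_positions]
            rpos = [r for r, _, _ in aln.match_positions]
            cigar = "".join(f"({ri + 1},{qi + 1})" for ri, qi, _ in aln.matches)
            orient = "+" if aln.orientation == "forward" else "-"
            fh.write(
                f"{eid}\t{aln.query_id}\t{aln.ref_id}"
                f"\t{min(qpos) + 1.0:.1f}\t{max(qpos) + 1.0:.1f}"
                f"\t{min(rpos) + 1.0:.1f}\t{max(rpos) + 1.0:.1f}"
                f"\t{orient}\t{aln.score:.2f}\t{cigar}\n"
            )


def read_xmap(path) -> list[dict]:
    """XMAP rows as dicts (site indices back to 0-based)."""
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_XMAP_COLS):
                raise FormatError("wrong column count", str(path), ln)
            pairs = []
            body = parts[9]
            for tok in body.strip(")(").split(")("):
                if tok:
                    a, b = tok.split(",")
                    pairs.append((int(a) - 1, int(b) - 1))
            out.append(
                {
                    "query_id": parts[1],
                    "ref_id": parts[2],
                    "qry_span": (float(parts[3]) - 1.0, float(parts[4]) - 1.0),
                    "ref_span": (float(parts[5]) - 1.0, float(parts[6]) - 1.0),
                    "orientation": "forward" if parts[7] == "+" else "flipped",
                    "score": float(parts[8]),
                    "matches": pairs,
                }
            )
    return out


# ---------------------------------------------------------------- reports / AGP

def write_discrepancy_tsv(discrepancies: list[Discrepancy], path) -> None:
    cols = ["kind", "query_id", "ref_start", "ref_end", "qry_start", "qry_end",
            "size_bp", "evidence"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in discrepancies:
            rs, re_ = d.ref_interval or ("", "")
            qs, qe = d.query_interval or ("", "")
            ev = ";".join(f"{k}={v}" for k, v in sorted(d.evidence.items(), key=lambda x: x[0]))
            fmt = lambda v: f"{v:.1f}" if isinstance(v, float) else str(v)
            fh.write(
                f"{d.kind}\t{d.query_id or ''}\t{fmt(rs)}\t{fmt(re_)}"
                f"\t{fmt(qs)}\t{fmt(qe)}\t{d.size_estimate_bp:.1f}\t{ev}\n"
            )


def write_agp(components: list[dict], path, object_id: str = "scaffold") -> None:
    """Minimal AGP v2.1 writer.

    Each component dict: {kind: 'W'|'N', length: int, name: str (W only),
    comp_start/comp_end/orientation optional for W}.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        pos = 1
        for idx, comp in enumerate(components, start=1):
            length = int(comp["length"])
            end = pos + length - 1
            if comp["kind"] == "W":
                fh.write(
                    f"{object_id}\t{pos}\t{end}\t{idx}\tW\t{comp['name']}"
                    f"\t{comp.get('comp_start', 1)}\t{comp.get('comp_end', length)}"
                    f"\t{comp.get('orientation', '+')}\n"
                )
            else:
                fh.write(
                    f"{object_id}\t{pos}\t{end}\t{idx}\tN\t{length}"
                    f"\tscaffold\tyes\tmap\n"
                )
            pos = end + 1


# ---------------------------------------------------------------- RunConfig

@dataclass
class RunConfig:
    """Full run configuration; validates nested invariants and round-trips
    losslessly through YAML."""

    channels: list[ChannelSpec] = field(
        default_factory=lambda: [ChannelSpec(**c) for c in load_defaults()["channels"]]
    )
    simulation: SimulationParams = field(default_factory=SimulationParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    alignment: AlignParams = field(default_factory=AlignParams)
    asmcheck: AsmParams = field(default_factory=AsmParams)
    seed: int = 0

    def validate(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate channel_id in config")
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = {
            "channels": [dataclasses.asdict(c) for c in self.channels],
            "simulation": dataclasses.asdict(self.simulation),
            "consensus": dataclasses.asdict(self.consensus),
            "alignment": dataclasses.asdict(self.alignment),
            "asmcheck": {**dataclasses.asdict(self.asmcheck)},
            "seed": self.seed,
        }
        d["asmcheck"]["exclusions"] = [list(x) for x in self.asmcheck.exclusions]
        d["asmcheck"]["align"] = dataclasses.asdict(self.asmcheck.align)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        if "channels" in d:
            kw["channels"] = [ChannelSpec(**c) for c in d["channels"]]
        if "simulation" in d:
            kw["simulation"] = SimulationParams(**d["simulation"])
        if "consensus" in d:
            kw["consensus"] = ConsensusParams(**d["consensus"])
        if "alignment" in d:
            kw["alignment"] = AlignParams(**d["alignment"])
        if "asmcheck" in d:
            a = dict(d["asmcheck"])
            align = AlignParams(**a.pop("align")) if "align" in a else AlignParams()
            a["exclusions"] = tuple(tuple(x) for x in a.get("exclusions", ()))
            kw["asmcheck"] = AsmParams(**a, align=align)
        if "seed" in d:
            kw["seed"] = int(d["seed"])
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            data = yaml.safe_load(io.StringIO(path_or_text))
        else:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
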