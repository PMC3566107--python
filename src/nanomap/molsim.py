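"""Synthetic single-molecule label data with known ground truth.

Emulates nanochannel imaging noise on full-length (Cre-linearized) clone
molecules. The generative order is fixed and documented: label dropout ->
false labels -> positional noise -> per-molecule scale -> optical-resolution
merging -> orientation flip. Coordinates are emitted in calibrated bp (the
physical stretch to a fraction of the B-DNA contour cancels out of calibrated
coordinates; only per-molecule stretch *variation* appears as length noise —
the mean stretch enters only the nm-scale report, see :func:`report_stretch`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._defaults import section
from .errors import ValidationError
from .motifmap import ReferenceMap

#: Rise per base pair of linear B-DNA, in nm.
BDNA_NM_PER_BP = 0.34

_D = section("simulation")


@dataclass(frozen=True)
class SimulationParams:
    coverage_per_clone: int = _D["coverage_per_clone"]
    label_efficiency: float = _D["label_efficiency"]
    false_label_rate: float = _D["false_label_rate"]  # per 100 kb per channel
    sizing_sd_bp: float = _D["sizing_sd_bp"]
    optical_resolution_bp: float = _D["optical_resolution_bp"]
    stretch_mean: float = _D["stretch_mean"]
    stretch_sd: float = _D["stretch_sd"]
    flip_probability: float = _D["flip_probability"]
    seed: int = _D["seed"]

    def validate(self) -> None:
        if self.coverage_per_clone < 1:
            raise ValidationError("coverage_per_clone must be >= 1")
        if not (0.0 < self.label_efficiency <= 1.0):
            raise ValidationError("label_efficiency must be in (0, 1]")
        for name in ("false_label_rate", "sizing_sd_bp", "optical_resolution_bp", "stretch_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 < self.stretch_mean <= 1.5):
            raise ValidationError("stretch_mean must be in (0, 1.5]")
        if not (0.0 <= self.flip_probability <= 1.0):
            raise ValidationError("flip_probability must be in [0, 1]")

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


@dataclass
class MoleculeTruth:
    source_id: str
    source_interval: tuple[float, float]
    orientation: str  # 'forward' | 'flipped'
    provenance: dict[int, list[str]] = field(default_factory=dict)


@dataclass
class MoleculeMap:
    """One imaged molecule: apparent length plus sorted per-channel labels."""

    molecule_id: str
    length_bp: float
    labels: dict[int, np.ndarray] = field(default_factory=dict)
    truth: MoleculeTruth | None = None

    def validate(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"{self.molecule_id}: non-positive length")
        for ch, pos in self.labels.items():
            if len(pos) and (pos[0] < 0 or pos[-1] > self.length_bp):
                raise ValidationError(f"{self.molecule_id}: channel {ch} label out of range")
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"{self.molecule_id}: channel {ch} labels not strictly increasing"
                )

    def flipped(self) -> "MoleculeMap":
        """Mirror image of this molecule (positions map to length - p)."""
        labels = {ch: (self.length_bp - pos)[::-1].copy() for ch, pos in self.labels.items()}
        truth = None
        if self.truth is not None:
            truth = MoleculeTruth(
                source_id=self.truth.source_id,
                source_interval=self.truth.source_interval,
                orientation="flipped" if self.truth.orientation == "forward" else "forward",
                provenance={ch: tags[::-1] for ch, tags in self.truth.provenance.items()},
            )
        return MoleculeMap(self.molecule_id, self.length_bp, labels, truth)


def merge_close_labels(
    positions: np.ndarray, resolution_bp: float, tags: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Merge same-channel labels closer than the optical resolution.

    Greedy left-to-right: a group opens at the leftmost unmerged label and
    absorbs labels within ``resolution_bp`` of the group's first member; the
    merged label sits at the arithmetic midpoint (mean) of the group. Keeping
    the window anchored at the group start stops long dense runs from
    collapsing to a single label, which is what the optics do.
    """
    n = len(positions)
    if tags is None:
        tags = [""] * n
    out_pos: list[float] = []
    out_tags: list[str] = []
    i = 0
    while i < n:
        j = i + 1
        while j < n and positions[j] - positions[i] < resolution_bp:
            j += 1
        out_pos.append(float(np.mean(positions[i:j])))
        out_tags.append("+".join(t for t in tags[i:j] if t))
        i = j
    return np.asarray(out_pos), out_tags


def simulate_molecules(source: ReferenceMap, params: SimulationParams) -> list[MoleculeMap]:
    """Simulate ``coverage_per_clone`` full-length molecules from ``source``.

    Deterministic given ``params.seed``; the random stream is consumed in a
    fixed order per molecule regardless of parameter values.
    """
    params.validate()
    if source.length_bp < 1000:
        raise ValidationError(f"source {source.map_id} shorter than 1 kb")

    rng = np.random.default_rng(params.seed)
    length = float(source.length_bp)
    channels = sorted(source.labels) or [1]
    molecules: list[MoleculeMap] = []

    for k in range(params.coverage_per_clone):
        scale = float(rng.normal(1.0, params.stretch_sd))
        scale = max(scale, 0.5)  # guard against pathological draws
        mol_labels: dict[int, np.ndarray] = {}
        mol_tags: dict[int, list[str]] = {}
        for ch in channels:
            true_pos = np.asarray(source.labels.get(ch, ()), dtype=float)
            keep = rng.random(len(true_pos)) < params.label_efficiency
            pos = true_pos[keep]
            tags = [f"{ch}:{i}" for i in np.flatnonzero(keep)]
            n_false = int(rng.poisson(params.false_label_rate * length / 1e5))
            false_pos = rng.uniform(0.0, length, n_false)
            pos = np.concatenate([pos, false_pos])
            tags += ["false"] * n_false
            noise = rng.normal(0.0, params.sizing_sd_bp, len(pos))
            pos = np.clip(pos + noise, 0.0, length)
            order = np.argsort(pos, kind="stable")
            pos = pos[order] * scale
            tags = [tags[i] for i in order]
            pos, tags = merge_close_labels(pos, params.optical_resolution_bp, tags)
            mol_labels[ch] = pos
            mol_tags[ch] = tags

        mol_len = length * scale
        flip = rng.random() < params.flip_probability
        truth = MoleculeTruth(
            source_id=source.map_id,
            source_interval=(0.0, float(source.length_bp)),
            orientation="forward",
            provenance=mol_tags,
        )
        mol = MoleculeMap(f"{source.map_id}_m{k}", mol_len, mol_labels, truth)
        if flip:
            mol = mol.flipped()
        mol.validate()
        molecules.append(mol)
    return molecules


def report_stretch(params: SimulationParams, molecule_length_bp: float) -> float:
    """Apparent molecule length in nm at the configured channel stretch."""
    if molecule_length_bp <= 0:
        raise ValidationError("molecule_length_bp must be > 0")
    return molecule_length_bp * BDNA_NM_PER_BP * params.stretch_mean
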