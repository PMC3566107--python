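"""Loader for the packaged default-parameter file (defaults live in config, not code)."""

from __future__ import annotations

import functools
from importlib import resources

import yaml


@functools.cache
def load_defaults() -> dict:
    text = resources.files("nanomap").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def section(name: str) -> dict:
    return dict(load_defaults()[name])
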