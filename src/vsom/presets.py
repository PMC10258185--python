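"""Bundled parameter presets (published untuned / perception / sickness sets)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def _table() -> dict:
    with resources.files("vsom.data").joinpath("presets.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def preset_dict(model: str, name: str) -> dict:
    """Raw parameter mapping for ``model`` in {svm, msom, pfm} and
    ``name`` in {untuned, perception, sickness}."""
    table = _table()
    try:
        return dict(table[model][name])
    except KeyError as exc:
        raise KeyError(f"no preset {model}/{name}") from exc


def sickness_weights(model: str) -> dict[str, float]:
    """Fitted conflict weights of the integrated sickness proxy."""
    return dict(_table()["sickness_weights"][model])
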