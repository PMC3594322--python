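"""Named construct profiles calibrated to published mean CER anchors."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .synthgen import CellGeometry, LocalizationProfile, calibrate_chrom_enrich

__all__ = ["load_catalog", "profile_for_target_cer"]


def profile_for_target_cer(
    name: str,
    target_cer: float,
    geometry: CellGeometry | None = None,
    **profile_kwargs,
) -> LocalizationProfile:
    """Profile whose noise-free true CER equals ``target_cer`` under ``geometry``."""
    geometry = geometry or CellGeometry()
    base = LocalizationProfile(name=name, **profile_kwargs)
    enrich = calibrate_chrom_enrich(target_cer, geometry, base)
    return LocalizationProfile(name=name, chrom_enrich=enrich, **profile_kwargs)


def load_catalog(
    path: str | Path | None = None,
    geometry: CellGeometry | None = None,
    names: list[str] | None = None,
) -> dict[str, LocalizationProfile]:
    """Load the construct catalogue, calibrating each profile to its target CER.

    With no ``path``, the packaged catalogue is used.  ``names`` restricts
    loading (and the calibration work) to a subset of constructs.
    """
    if path is None:
        text = resources.files("cermap").joinpath("data/constructs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)["constructs"]
    if names is not None:
        missing = set(names) - set(raw)
        if missing:
            raise KeyError(f"unknown constructs: {sorted(missing)}")
        raw = {k: raw[k] for k in names}
    catalog = {}
    for name, entry in raw.items():
        entry = dict(entry)
        target = float(entry.pop("target_cer"))
        catalog[name] = profile_for_target_cer(name, target, geometry, **entry)
    return catalog
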