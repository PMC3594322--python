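"""Disk formats: multi-page TIFF cells, JSON sidecars, cohort manifests.

A cell is stored as a 4-page TIFF — page 1 the fluorescence image
(float32), pages 2–4 the cell / plate-truth / hand-ROI masks as uint8
0/255 — with a JSON sidecar carrying the truth values and seed.  The
background mask is recomputed as the complement of the stored cell mask
padded by a margin when reading user data; for package-generated cells it
is stored too (page 5).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthgen import SyntheticCell

__all__ = ["read_cell", "write_cell", "write_manifest"]

_PAGES = ("fluor", "cell_mask", "chrom_mask", "chrom_roi", "background_mask")


def write_cell(cell: SyntheticCell, path: str | Path) -> Path:
    """Write one cell as multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    pages = [
        cell.fluor_image.astype(np.float32),
        (cell.cell_mask_truth.astype(np.uint8) * 255),
        (cell.chrom_mask_truth.astype(np.uint8) * 255),
        (cell.chrom_roi.astype(np.uint8) * 255),
        (cell.background_mask.astype(np.uint8) * 255),
    ]
    with tifffile.TiffWriter(path) as tif:
        for page in pages:
            tif.write(page, contiguous=False)
    sidecar = {
        "cell_id": cell.cell_id,
        "profile": cell.profile_name,
        "seed": cell.seed,
        "true_cer": cell.true_cer,
        "expression": cell.expression,
        "plate_defined": cell.plate_defined,
        "saturated": cell.saturated,
        "pages": list(_PAGES),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_cell(path: str | Path) -> SyntheticCell:
    """Read a cell written by :func:`write_cell`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    meta = json.loads(path.with_suffix(".json").read_text())
    return SyntheticCell(
        fluor_image=np.asarray(pages[0], dtype=float),
        cell_mask_truth=pages[1] > 0,
        chrom_mask_truth=pages[2] > 0,
        chrom_roi=pages[3] > 0,
        background_mask=pages[4] > 0,
        true_cer=float(meta["true_cer"]),
        seed=int(meta["seed"]),
        expression=float(meta["expression"]),
        plate_defined=bool(meta["plate_defined"]),
        saturated=bool(meta["saturated"]),
        cell_id=meta["cell_id"],
        profile_name=meta["profile"],
    )


def write_manifest(cells: list[SyntheticCell], path: str | Path) -> Path:
    """Cohort manifest CSV: one generated cell per row."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "construct": [c.profile_name for c in cells],
            "seed": [c.seed for c in cells],
            "true_cer": [c.true_cer for c in cells],
            "expression": [c.expression for c in cells],
            "plate_defined": [c.plate_defined for c in cells],
            "saturated": [c.saturated for c in cells],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path
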