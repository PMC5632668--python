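"""Reading and writing the package's file formats.

Images are 8- or 16-bit grayscale PNG/TIFF (Pillow); importance maps are
grayscale PNG rescaled to [0, 1] or CSV grids; masks are 0/255 PNGs.
Tabular artefacts (scores, design assignments, manifests, trials) are plain
CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .design_balancer import BALANCE_COVARIATES, DesignAssignment, PairScore
from .image_metrics import ChangeRegion, ImageGeometry, ImportanceMap, LuminanceImage


def load_luminance(path, extent_deg_x: float = 18.6) -> LuminanceImage:
    """Load a grayscale PNG/TIFF as a luminance image."""
    arr = np.asarray(Image.open(path).convert("I")).astype(float)
    h, w = arr.shape
    return LuminanceImage(arr, ImageGeometry.from_extent(w, h, extent_deg_x))


def save_luminance_png(img: LuminanceImage, path) -> None:
    vals = img.values
    if vals.max() > 65535 or not np.allclose(vals, np.round(vals)):
        raise ValueError("luminance image must be integer-valued <= 65535 for PNG")
    dtype = np.uint8 if vals.max() <= 255 else np.uint16
    Image.fromarray(vals.astype(dtype)).save(path)


def load_importance(path, n_observers: int = 5) -> ImportanceMap:
    """Importance map from a grayscale PNG (rescaled /255) or CSV grid."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        vals = pd.read_csv(path, header=None).to_numpy(dtype=float)
    else:
        vals = np.asarray(Image.open(path).convert("L")).astype(float) / 255.0
    return ImportanceMap(values=vals, n_observers=n_observers)


def save_importance_png(imap: ImportanceMap, path) -> None:
    Image.fromarray(np.round(imap.values * 255).astype(np.uint8), mode="L").save(path)


def load_mask(path) -> ChangeRegion:
    arr = np.asarray(Image.open(path).convert("L"))
    return ChangeRegion(mask=arr > 127)


def save_mask_png(region: ChangeRegion, path) -> None:
    Image.fromarray(np.where(region.mask, 255, 0).astype(np.uint8), mode="L").save(path)


def scores_to_frame(scores: list[PairScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {
            "pair_id": s.pair_id,
            "source_image_id": s.source_image_id,
            "ce_change": s.ce_change,
            "si_change": s.si_change,
        }
        row.update(s.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_scores(df: pd.DataFrame) -> list[PairScore]:
    cov_cols = [c for c in df.columns if c in BALANCE_COVARIATES]
    return [
        PairScore(
            pair_id=str(r["pair_id"]),
            source_image_id=str(r["source_image_id"]),
            ce_change=float(r["ce_change"]),
            si_change=float(r["si_change"]),
            covariates={c: float(r[c]) for c in cov_cols},
        )
        for r in df.to_dict("records")
    ]


def load_scores(path) -> list[PairScore]:
    return frame_to_scores(pd.read_csv(path))


def save_scores(scores: list[PairScore], path) -> None:
    scores_to_frame(scores).to_csv(path, index=False)


def assignment_to_frame(assignment: DesignAssignment) -> pd.DataFrame:
    membership: dict[str, list[int]] = {p: [] for p in assignment.condition}
    for sid, pids in assignment.subsets.items():
        for p in pids:
            membership[p].append(sid)
    rows = [
        {
            "pair_id": pid,
            "condition": assignment.condition[pid],
            "source_image_id": assignment.source.get(pid, ""),
            "selected": pid in set(assignment.selected),
            "subset_ids": ";".join(map(str, sorted(membership[pid]))),
        }
        for pid in assignment.condition
    ]
    return pd.DataFrame(rows)


def save_assignment(assignment: DesignAssignment, path) -> None:
    assignment_to_frame(assignment).to_csv(path, index=False)


def load_assignment(path) -> DesignAssignment:
    df = pd.read_csv(path, keep_default_na=False)
    condition = dict(zip(df["pair_id"], df["condition"]))
    source = dict(zip(df["pair_id"], df["source_image_id"].astype(str)))
    selected = [r["pair_id"] for r in df.to_dict("records") if r["selected"] in (True, "True")]
    subsets: dict[int, list[str]] = {}
    for r in df.to_dict("records"):
        ids = str(r["subset_ids"])
        if ids:
            for sid in ids.split(";"):
                subsets.setdefault(int(sid), []).append(r["pair_id"])
    return DesignAssignment(
        condition=condition, selected=selected, source=source, subsets=subsets
    )
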