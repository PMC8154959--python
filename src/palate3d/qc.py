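"""Quality-control outputs and small summary statistics.

Per-slice segmentation QC, the per-slice transform table, and the lateral
deviation tally used when scoring shelf-elevation asymmetry across embryos
(a shelf pair is "left-deviated" when the left shelf is still vertical while
the right is already horizontal, and vice versa).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

from .errors import ParameterError

__all__ = ["deviation_percentages", "slice_qc_csv", "transform_table_csv"]


def deviation_percentages(n_left_deviated: int, n_right_deviated: int,
                          ndigits: int = 1) -> dict[str, float]:
    """Percentages of laterally deviated embryos by side, rounded.

    ``n_left_deviated`` counts embryos with a vertical left / horizontal
    right shelf; ``n_right_deviated`` the mirror case.  With counts 7 and 8
    the split is 46.7% / 53.3%.
    """
    if n_left_deviated < 0 or n_right_deviated < 0:
        raise ParameterError("counts must be non-negative")
    total = n_left_deviated + n_right_deviated
    if total == 0:
        raise ParameterError("at least one deviated embryo required")
    return {
        "left_pct": round(100.0 * n_left_deviated / total, ndigits),
        "right_pct": round(100.0 * n_right_deviated / total, ndigits),
        "n": total,
    }


def slice_qc_csv(masks, path) -> Path:
    """Write per-slice segmentation QC: index, area, centroid, degeneracy."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slice_index", "area_px", "centroid_row", "centroid_col",
                    "degenerate"])
        for i, m in enumerate(masks):
            cr, cc = m.centroid if m.centroid is not None else ("", "")
            w.writerow([i, m.area_px, cr, cc, int(m.degenerate)])
    return path


def transform_table_csv(aligned, path) -> Path:
    """Write the per-slice transform table of an aligned stack."""
    path = Path(path)
    dice = list(aligned.pairwise_dice) + [""]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slice_index", "theta_deg", "t_row", "t_col",
                    "dice_to_next"])
        for i, T in enumerate(aligned.transforms):
            w.writerow([i, math.degrees(T.theta), T.t_row, T.t_col, dice[i]])
    return path
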