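"""Pixelwise segmentation metrics and the vertical cup-to-disc ratio.

For each structure (disc, cup) a predicted binary plane S is compared with
the ground-truth plane G:

    overlap error  E   = 1 - |S ∩ G| / |S ∪ G|          (1 - IoU)
    sensitivity    SEN = TP / (TP + FN)
    specificity    SPE = TN / (TN + FP)

TP/TN/FP/FN are pixel counts over the evaluated plane. The vertical
cup-to-disc ratio (vCDR) — the clinical screening quantity — is the ratio
of the cup's vertical (row) extent to the disc's.

Empty-mask conventions: E = 0 when both masks are empty; SEN/SPE with a
zero denominator are reported as NaN and flagged so dataset means can
exclude them explicitly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import LabelVolume


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    """Per-image metric bundle for disc and cup, plus both vCDRs."""

    od_e: float
    od_sen: float
    od_spe: float
    cup_e: float
    cup_sen: float
    cup_spe: float
    vcdr_pred: float
    vcdr_true: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_planes(s: np.ndarray, g: np.ndarray):
    s = np.asarray(s)
    g = np.asarray(g)
    if s.shape != g.shape:
        raise ValueError(f"plane shape mismatch: {s.shape} vs {g.shape}")
    if not np.isin(s, (0, 1)).all() or not np.isin(g, (0, 1)).all():
        raise ValueError("planes must be binary")
    return s.astype(bool), g.astype(bool)


def confusion_counts(s: np.ndarray, g: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts of prediction ``s`` against ground truth ``g``."""
    s, g = _check_planes(s, g)
    tp = int(np.sum(s & g))
    tn = int(np.sum(~s & ~g))
    fp = int(np.sum(s & ~g))
    fn = int(np.sum(~s & g))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def overlap_error(s: np.ndarray, g: np.ndarray) -> float:
    """1 - IoU; zero when both masks are empty."""
    s, g = _check_planes(s, g)
    union = int(np.sum(s | g))
    if union == 0:
        return 0.0
    return 1.0 - int(np.sum(s & g)) / union


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when the ground truth has no positives."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else float("nan")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when the ground truth has no negatives."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else float("nan")


def vertical_cdr(vol: LabelVolume) -> float:
    """Vertical cup-to-disc ratio from a label volume.

    Row extents are inclusive pixel counts (max_row - min_row + 1). An
    empty cup gives 0; an empty disc is rejected (the ratio is undefined).
    """
    disc_rows = np.flatnonzero(vol.disc.any(axis=1))
    if disc_rows.size == 0:
        raise ValueError("disc plane is empty; vCDR is undefined")
    cup_rows = np.flatnonzero(vol.cup.any(axis=1))
    if cup_rows.size == 0:
        return 0.0
    cup_ext = cup_rows[-1] - cup_rows[0] + 1
    disc_ext = disc_rows[-1] - disc_rows[0] + 1
    return float(cup_ext / disc_ext)


def evaluate(pred: LabelVolume, truth: LabelVolume) -> EvalReport:
    """All six structure metrics plus predicted and true vCDR."""
    if pred.shape != truth.shape:
        raise ValueError(f"volume shape mismatch: {pred.shape} vs {truth.shape}")
    cd = confusion_counts(pred.disc, truth.disc)
    cc = confusion_counts(pred.cup, truth.cup)
    try:
        vp = vertical_cdr(pred)
    except ValueError:
        vp = float("nan")
    return EvalReport(
        od_e=overlap_error(pred.disc, truth.disc),
        od_sen=sensitivity(cd),
        od_spe=specificity(cd),
        cup_e=overlap_error(pred.cup, truth.cup),
        cup_sen=sensitivity(cc),
        cup_spe=specificity(cc),
        vcdr_pred=vp,
        vcdr_true=vertical_cdr(truth),
    )


def evaluate_many(pairs) -> pd.DataFrame:
    """Per-image metric rows for (pred, truth) volume pairs."""
    rows = [evaluate(p, t).to_dict() for p, t in pairs]
    return pd.DataFrame(rows)


def pooled_evaluate(pairs) -> dict:
    """Dataset-wide metrics from pooled pixel counts (alternative to the
    per-image mean): confusion counts are summed over all images before the
    ratios are formed, and overlap error uses pooled intersection/union."""
    agg = {k: 0 for k in ("disc_tp", "disc_fp", "disc_fn", "disc_tn",
                          "cup_tp", "cup_fp", "cup_fn", "cup_tn")}
    for pred, truth in pairs:
        for name, sp, gp in (("disc", pred.disc, truth.disc),
                             ("cup", pred.cup, truth.cup)):
            c = confusion_counts(sp, gp)
            agg[f"{name}_tp"] += c.tp
            agg[f"{name}_fp"] += c.fp
            agg[f"{name}_fn"] += c.fn
            agg[f"{name}_tn"] += c.tn
    out = {}
    for name in ("disc", "cup"):
        c = ConfusionCounts(tp=agg[f"{name}_tp"], tn=agg[f"{name}_tn"],
                            fp=agg[f"{name}_fp"], fn=agg[f"{name}_fn"])
        union = c.tp + c.fp + c.fn
        key = "od" if name == "disc" else "cup"
        out[f"{key}_e"] = 1.0 - c.tp / union if union else 0.0
        out[f"{key}_sen"] = sensitivity(c)
        out[f"{key}_spe"] = specificity(c)
    return out


def summarize(frame: pd.DataFrame) -> dict:
    """Mean of each metric column, ignoring NaN, with exclusion counts."""
    summary = {}
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        summary[col] = float(np.mean(vals[ok])) if ok.any() else float("nan")
        summary[f"{col}_n_excluded"] = int(np.sum(~ok))
    summary["vcdr_abs_error"] = float(
        np.nanmean(np.abs(frame["vcdr_pred"] - frame["vcdr_true"]))
    )
    return summary


def write_report(frame: pd.DataFrame, csv_path, json_path) -> None:
    frame.to_csv(csv_path, index=False)
    Path(json_path).write_text(json.dumps(summarize(frame), indent=2))
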