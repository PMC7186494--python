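"""Screening-power evaluation: hit lists, enrichment factors, ROC/AUC.

A hit list holds one row per parent molecule: states (protonation,
chirality) are collapsed to the lowest — best — score among those that
survived the QM stage, and molecules whose every state failed are excluded
from both numerator and totals. Lower score means better throughout.

EF(x) is the fraction of true ligands in the top x% of the ranked list
divided by the ligand fraction overall; the top set is the ceiling
N_x = ceil(x * N_total / 100) so it is never empty (the rounding rule is
declared in the metrics output). ROC/AUC sweep the score threshold, with
ties credited half a pair, which makes the AUC identical to the
Mann-Whitney pair-counting statistic. EF(1) and EF(2) are the headline
early-enrichment numbers; EF(5), EF(10) and AUC complete the default
report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from .core import LibraryManifest
from .scoring import ScoreRecord

logger = logging.getLogger(__name__)

DEFAULT_EF_PERCENTAGES = (1.0, 2.0, 5.0, 10.0)


@dataclass
class HitList:
    parent_ids: list[str]
    scores: np.ndarray  # ascending; lower = better
    labels: np.ndarray  # True = ligand
    excluded: list[str] = field(default_factory=list)  # states dropped as failed

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.parent_ids) == len(self.scores) == len(self.labels)):
            raise ValueError("hit-list columns must have equal length")
        if np.any(np.diff(self.scores) < 0):
            raise ValueError("hit-list must be sorted by ascending score")

    @property
    def n_total(self) -> int:
        return len(self.scores)

    @property
    def hits_total(self) -> int:
        return int(np.sum(self.labels))


def build_hitlist(
    records: list[ScoreRecord], manifest: LibraryManifest | None = None
) -> HitList:
    """Collapse per-state score records (one variant) to per-molecule rows.

    Failed records are logged and excluded; surviving states contribute
    their minimum score per parent. Ties are broken by parent id so the
    ordering is stable across runs.
    """
    variants = {r.variant for r in records}
    if len(variants) > 1:
        raise ValueError(f"records mix variants {sorted(variants)}; build one hit-list per variant")
    excluded = [r.state_id for r in records if not r.converged]
    best: dict[str, float] = {}
    labels: dict[str, bool] = {}
    for r in records:
        if not r.converged:
            continue
        if manifest is not None:
            is_lig = manifest.is_ligand(r.state_id)
        else:
            is_lig = getattr(r, "is_ligand", False)
        prev = best.get(r.parent_id)
        if prev is None or r.qmds < prev:
            best[r.parent_id] = r.qmds
        labels[r.parent_id] = is_lig
    if not best:
        raise ValueError("every score record failed; no hit-list to build")
    order = sorted(best, key=lambda pid: (best[pid], pid))
    return HitList(
        parent_ids=order,
        scores=np.array([best[p] for p in order]),
        labels=np.array([labels[p] for p in order]),
        excluded=excluded,
    )


def hitlist_from_arrays(scores, labels, parent_ids=None) -> HitList:
    """Hit list straight from score/label vectors (oracle and plotting use)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if parent_ids is None:
        parent_ids = [f"m{i:06d}" for i in range(len(scores))]
    order = sorted(range(len(scores)), key=lambda i: (scores[i], parent_ids[i]))
    return HitList(
        parent_ids=[parent_ids[i] for i in order],
        scores=scores[order],
        labels=labels[order],
    )


def enrichment_factor(hitlist: HitList, x: float) -> float:
    """EF(x) with the ceiling top-set rule; EF(100) is exactly 1."""
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    if hitlist.hits_total == 0:
        raise ValueError("EF undefined: hit-list contains no ligands")
    n_top = math.ceil(x * hitlist.n_total / 100.0)
    hits_top = int(np.sum(hitlist.labels[:n_top]))
    return (hits_top / n_top) / (hitlist.hits_total / hitlist.n_total)


def roc_auc(hitlist: HitList) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (FPR, TPR) and AUC by threshold sweep on the scores.

    Lower score = better, so the decision value is the negated score; tied
    scores advance the curve diagonally, crediting 0.5 per tied
    ligand-decoy pair (Mann-Whitney equivalence).
    """
    if hitlist.hits_total == 0 or hitlist.hits_total == hitlist.n_total:
        raise ValueError("ROC needs both ligands and decoys in the hit-list")
    fpr, tpr, _ = roc_curve(hitlist.labels.astype(int), -hitlist.scores)
    return fpr, tpr, float(sk_auc(fpr, tpr))


def enrichment_plot_data(hitlist: HitList) -> tuple[np.ndarray, np.ndarray]:
    """(% screened, % ligands found) step curve from (0,0) to (100,100)."""
    n = hitlist.n_total
    found = np.concatenate([[0], np.cumsum(hitlist.labels)])
    screened = np.arange(n + 1) / n * 100.0
    ligands = found / max(hitlist.hits_total, 1) * 100.0
    return screened, ligands


def evaluate(
    hitlist: HitList, ef_percentages: tuple[float, ...] = DEFAULT_EF_PERCENTAGES
) -> dict[str, float]:
    """Default screening-power report."""
    out: dict[str, float] = {}
    for x in ef_percentages:
        key = f"EF{x:g}"
        out[key] = enrichment_factor(hitlist, x)
    _, _, out["AUC"] = roc_auc(hitlist)
    out["N_total"] = hitlist.n_total
    out["Hits_total"] = hitlist.hits_total
    out["N_excluded_states"] = len(hitlist.excluded)
    return out


def write_metrics(metrics: dict[str, float], path: str | Path) -> None:
    df = pd.DataFrame([{"metric": k, "value": v} for k, v in metrics.items()])
    with open(path, "w") as fh:
        fh.write("# top-set rounding: N_x = ceil(x * N_total / 100)\n")
        df.to_csv(fh, sep="\t", index=False)


def write_curves(hitlist: HitList, path: str | Path) -> None:
    fpr, tpr, _ = roc_auc(hitlist)
    screened, ligands = enrichment_plot_data(hitlist)
    roc_df = pd.DataFrame({"curve": "roc", "x": fpr, "y": tpr})
    enr_df = pd.DataFrame({"curve": "enrichment", "x": screened, "y": ligands})
    pd.concat([roc_df, enr_df]).to_csv(path, index=False)


def plot_curves(hitlist: HitList, path: str | Path, title: str = "") -> None:
    """ROC + enrichment plots with the random diagonal, saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr, tpr, auc_val = roc_auc(hitlist)
    screened, ligands = enrichment_plot_data(hitlist)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(fpr, tpr, label=f"AUC = {auc_val:.2f}")
    ax1.plot([0, 1], [0, 1], "k:", label="random")
    ax1.set_xlabel("FPR")
    ax1.set_ylabel("TPR")
    ax1.legend()
    ax2.plot(screened, ligands)
    ax2.plot([0, 100], [0, 100], "k:")
    ax2.set_xlabel("% screened")
    ax2.set_ylabel("% ligands found")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
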