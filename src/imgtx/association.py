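"""Transcriptome–neuroimaging spatial association.

Gene expression at donor tissue samples is correlated, gene by gene, with
the case–control t-statistic sampled around each sample's MNI coordinate.
The t-map is the *uncorrected* voxel-wise map (pre cluster thresholding);
each sample's value is the mean t over in-mask voxels whose centre lies
within a 3 mm sphere of its coordinate.  Per-gene Pearson correlations are
Bonferroni-corrected at alpha / n_genes, and the final gene set is the
intersection of the significant genes with a supplied risk-gene list
(symbols compared upper-case).

``TranscriptomicAssociation`` is the model object; ``fit`` returns an
:class:`AssociationResults` with the per-gene table, the final gene set and
a ``summary`` view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import GeneExpressionMatrix
from .images import StatMap, voxel_centers_mm

logger = logging.getLogger(__name__)

__all__ = [
    "sample_tmap_spheres",
    "genewise_correlation",
    "bonferroni_threshold",
    "intersect_risk_genes",
    "load_risk_genes",
    "TranscriptomicAssociation",
    "AssociationResults",
]


def sample_tmap_spheres(
    tmap: StatMap,
    coords_mm: np.ndarray,
    radius_mm: float = 3.0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean t within a sphere around each coordinate.

    A voxel belongs to a sphere when its centre lies within ``radius_mm``
    (Euclidean, mm).  Returns ``(means, n_voxels)``; coordinates with no
    in-mask voxel get NaN and are meant to be excluded downstream.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be positive, got {radius_mm}")
    coords_mm = np.atleast_2d(np.asarray(coords_mm, float))
    if not np.isfinite(coords_mm).all():
        raise ValueError("sample coordinates must be finite")
    if mask is None:
        mask = np.ones(tmap.data.shape, bool)
    mask = np.asarray(mask, bool)

    centers = voxel_centers_mm(tmap.data.shape, tmap.affine)[mask.ravel()]
    values = tmap.data[mask]
    means = np.full(len(coords_mm), np.nan)
    counts = np.zeros(len(coords_mm), int)
    r2 = radius_mm**2
    for i, c in enumerate(coords_mm):
        d2 = ((centers - c) ** 2).sum(axis=1)
        sel = d2 <= r2
        counts[i] = int(sel.sum())
        if counts[i]:
            means[i] = values[sel].mean()
    n_empty = int((counts == 0).sum())
    if n_empty:
        logger.info("sphere sampling: %d coordinate(s) with no in-mask voxel", n_empty)
    return means, counts


def genewise_correlation(matrix: pd.DataFrame, t_values: np.ndarray) -> pd.DataFrame:
    """Pearson r and two-sided p of every gene column against ``t_values``.

    Zero-variance genes get r = 0, p = 1 and a ``degenerate`` flag.
    """
    t_values = np.asarray(t_values, float)
    if len(t_values) != len(matrix):
        raise ValueError("t_values must align with matrix rows")
    n = len(t_values)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    X = matrix.to_numpy(float)
    Xc = X - X.mean(axis=0)
    tc = t_values - t_values.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    if st == 0:
        raise ValueError("sampled t-values are constant")
    degenerate = sx == 0
    denom = np.where(degenerate, 1.0, sx * st)
    r = (Xc * tc[:, None]).sum(axis=0) / denom
    r = np.clip(np.where(degenerate, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    if degenerate.any():
        logger.info("gene-wise correlation: %d zero-variance gene(s)", int(degenerate.sum()))
    return pd.DataFrame(
        {"r": r, "p": p, "n": n, "degenerate": degenerate}, index=matrix.columns
    )


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / n."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def load_risk_genes(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line risk-gene list (blank lines ignored)."""
    lines = Path(path).read_text().splitlines()
    genes = [ln.strip() for ln in lines if ln.strip()]
    return genes


def intersect_risk_genes(result: pd.DataFrame, risk_genes: list[str]) -> pd.DataFrame:
    """Flag risk-list membership and the final (significant AND risk) set.

    ``result`` must carry a boolean ``significant`` column; symbols are
    compared upper-case.  Raises on an empty risk list; warns when the risk
    list is disjoint from the matrix genes.
    """
    risk = {g.upper() for g in risk_genes}
    if not risk:
        raise ValueError("risk-gene list is empty")
    out = result.copy()
    upper = out.index.str.upper()
    out["risk_gene"] = upper.isin(risk)
    if not out["risk_gene"].any():
        logger.warning("risk-gene list shares no symbols with the expression matrix")
    out["final"] = out["significant"] & out["risk_gene"]
    return out


class TranscriptomicAssociation:
    """Gene-wise spatial association between expression and a t-map.

    Parameters
    ----------
    tmap : StatMap
        Uncorrected voxel-wise t-map of the group difference.
    expression : GeneExpressionMatrix
        Processed samples x genes matrix with MNI sample coordinates.
    mask : ndarray of bool, optional
        Analysis mask for sphere extraction (defaults to all voxels).
    """

    def __init__(
        self,
        tmap: StatMap,
        expression: GeneExpressionMatrix,
        mask: np.ndarray | None = None,
    ):
        self.tmap = tmap
        self.expression = expression
        self.mask = mask

    def fit(
        self,
        risk_genes: list[str] | None = None,
        alpha: float = 0.05,
        radius_mm: float = 3.0,
    ) -> "AssociationResults":
        t_at_samples, counts = sample_tmap_spheres(
            self.tmap, self.expression.coords_mm, radius_mm, self.mask
        )
        usable = counts > 0
        table = genewise_correlation(
            self.expression.data.loc[usable], t_at_samples[usable]
        )
        thr = bonferroni_threshold(alpha, table.shape[0])
        table["significant"] = table["p"] < thr
        if risk_genes is not None:
            table = intersect_risk_genes(table, risk_genes)
        return AssociationResults(
            self, table, alpha=alpha, threshold=thr, radius_mm=radius_mm,
            n_samples_used=int(usable.sum()),
        )


@dataclass
class AssociationResults:
    """Per-gene association table with Bonferroni and risk-list flags."""

    model: TranscriptomicAssociation
    table: pd.DataFrame
    alpha: float
    threshold: float
    radius_mm: float
    n_samples_used: int

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def final_genes(self) -> list[str]:
        if "final" not in self.table:
            return []
        return list(self.table.index[self.table["final"]])

    def summary(self, top: int = 20) -> pd.DataFrame:
        cols = [c for c in ("r", "p", "significant", "risk_gene", "final") if c in self.table]
        return self.table.sort_values("p")[cols].head(top)

    def __str__(self) -> str:
        n_genes = self.table.shape[0]
        lines = [
            f"TranscriptomicAssociation: {n_genes} genes x {self.n_samples_used} samples, "
            f"sphere radius {self.radius_mm} mm",
            f"Bonferroni threshold: {self.alpha}/{n_genes} = {self.threshold:.4g}",
            f"significant genes: {len(self.significant_genes)}",
        ]
        if "final" in self.table:
            lines.append(
                f"final (significant AND risk) genes: {len(self.final_genes)} "
                f"{sorted(self.final_genes)}"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")
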