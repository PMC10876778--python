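"""Donor microarray processing into a normalized sample x gene matrix.

The pipeline mirrors current practice for Allen-atlas-style expression
bundles and runs in a fixed order:

1. intensity-based probe filtering — keep probes above background in at
   least 50% of samples, donors pooled (the exact-50% case is retained);
2. RNA-seq-guided probe selection — per gene, among probes whose pooled
   (donor, structure)-level profile correlates with the RNA-seq reference
   at Pearson r >= 0.2, keep the best-correlated probe; genes absent from
   the RNA-seq platform or with no qualifying probe are dropped;
3. sample restriction — left-hemisphere cortical samples whose MNI
   coordinate falls inside a gray-matter mask;
4. scaled-robust-sigmoid (SRS) normalization, per donor: within-sample
   across genes, then within-gene across samples;
5. differential stability (DS) — per gene, the mean over donor pairs of
   the Spearman correlation between the donors' structure-mean expression
   profiles — followed by retention of the top-50% DS genes.

The output is a :class:`GeneExpressionMatrix`: samples x genes in [0, 1]
with row-linked annotations and the per-gene DS values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .images import ActivityMap, mm_to_voxel

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionBundle",
    "GeneExpressionMatrix",
    "filter_probes_intensity",
    "select_probes_by_rnaseq",
    "restrict_samples",
    "srs_normalize",
    "differential_stability",
    "select_top_ds",
    "process_expression_bundle",
]

IQR_NORMAL_CONSISTENCY = 1.35  # IQR of a standard normal, to 2 decimals


@dataclass
class ExpressionBundle:
    """Raw donor expression bundle.

    Attributes
    ----------
    probes : DataFrame indexed by probe id with a ``gene`` column.
    expression : DataFrame, probes x samples, intensity on a log2-like scale.
    noise_flags : DataFrame, probes x samples, True where above background.
    rnaseq : DataFrame, genes x pooled (donor, structure) columns named
        ``"<donor>|<structure>"``; the reference profile for probe selection.
    samples : DataFrame indexed by sample id with columns ``donor``,
        ``mni_x/mni_y/mni_z``, ``hemisphere`` ("L"/"R"), ``tissue_class``
        ("cortex"/"subcortex"), ``structure``.
    """

    probes: pd.DataFrame
    expression: pd.DataFrame
    noise_flags: pd.DataFrame
    rnaseq: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.noise_flags.index) or not (
            self.expression.columns.equals(self.noise_flags.columns)
        ):
            raise ValueError("noise-flag table must align with the intensity table")
        if not self.expression.columns.equals(self.samples.index):
            raise ValueError("expression columns must match sample annotations")

    FILES = {
        "probes": "probes.tsv",
        "expression": "expression.tsv",
        "noise_flags": "noise_flags.tsv",
        "rnaseq": "rnaseq.tsv",
        "samples": "samples.tsv",
    }

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self.FILES.items():
            getattr(self, attr).to_csv(outdir / fname, sep="\t")

    @classmethod
    def load(cls, indir: str | Path) -> "ExpressionBundle":
        indir = Path(indir)
        frames = {
            attr: pd.read_csv(indir / fname, sep="\t", index_col=0)
            for attr, fname in cls.FILES.items()
        }
        frames["noise_flags"] = frames["noise_flags"].astype(bool)
        return cls(**frames)


@dataclass
class GeneExpressionMatrix:
    """Normalized samples x genes matrix with annotations and DS values."""

    data: pd.DataFrame          # samples x genes, values in [0, 1]
    annotations: pd.DataFrame   # indexed like data rows
    ds: pd.Series               # per retained gene

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.annotations.index):
            raise ValueError("annotation rows must match matrix rows")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        vals = self.data.to_numpy()
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError("normalized expression must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def coords_mm(self) -> np.ndarray:
        return self.annotations[["mni_x", "mni_y", "mni_z"]].to_numpy(float)

    def save(self, path: str | Path, ds_path: str | Path | None = None) -> None:
        out = pd.concat([self.annotations, self.data], axis=1)
        out.to_csv(path, sep="\t")
        if ds_path is not None:
            self.ds.rename("ds").to_csv(ds_path, sep="\t")


def filter_probes_intensity(
    expression: pd.DataFrame, noise_flags: pd.DataFrame, min_prop: float = 0.5
) -> pd.Index:
    """Probes above background in at least ``min_prop`` of samples, pooled.

    Pooling is across all donors' samples; the exactly-at-threshold case is
    retained (inclusive >=).
    """
    if not expression.index.equals(noise_flags.index):
        raise ValueError("flag table must align with intensity table")
    prop = noise_flags.mean(axis=1)
    kept = expression.index[prop >= min_prop]
    logger.info("intensity filter: kept %d / %d probes", len(kept), len(expression))
    return kept


def _pooled_structure_profile(
    values: pd.Series, samples: pd.DataFrame
) -> pd.Series:
    """Mean intensity per (donor, structure), indexed ``"donor|structure"``."""
    key = samples["donor"].astype(str) + "|" + samples["structure"].astype(str)
    return values.groupby(key.to_numpy()).mean()


def select_probes_by_rnaseq(
    probes: pd.DataFrame,
    expression: pd.DataFrame,
    rnaseq: pd.DataFrame,
    samples: pd.DataFrame,
    min_r: float = 0.2,
) -> pd.Series:
    """Representative probe per gene by correlation with RNA-seq.

    For every gene present on both platforms, each candidate probe's
    (donor, structure)-pooled profile is correlated (Pearson) with the
    gene's RNA-seq profile over the shared columns; probes with r < ``min_r``
    (or undefined r) are excluded and the best remaining probe is chosen.
    Returns a gene -> probe id mapping; genes with no qualifying probe are
    absent.
    """
    genes_common = probes["gene"].isin(rnaseq.index)
    candidates = probes[genes_common]
    key = (samples["donor"].astype(str) + "|" + samples["structure"].astype(str)).to_numpy()

    # pooled profile for every candidate probe at once
    prof = expression.loc[candidates.index].T.groupby(key).mean().T  # probes x keys
    shared = prof.columns.intersection(rnaseq.columns)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared (donor, structure) units for probe selection")

    X = prof[shared].to_numpy(float)
    R = rnaseq.loc[candidates["gene"], shared].to_numpy(float)  # aligned to probes
    Xc = X - X.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sr = np.sqrt((Rc**2).sum(axis=1))
    ok = (sx > 0) & (sr > 0)  # undefined correlation counts as r < min_r
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ok, (Xc * Rc).sum(axis=1) / np.where(ok, sx * sr, 1.0), -np.inf)
    r = np.where(r >= min_r, r, -np.inf)

    frame = pd.DataFrame(
        {"gene": candidates["gene"].to_numpy(), "r": r}, index=candidates.index
    )
    frame = frame[np.isfinite(frame["r"])]
    best_idx = frame.groupby("gene")["r"].idxmax()
    mapping = pd.Series(best_idx.to_numpy(), index=best_idx.index, name="probe", dtype=object)
    mapping.index.name = "gene"
    logger.info(
        "probe selection: %d genes kept of %d with RNA-seq overlap",
        len(mapping), candidates["gene"].nunique(),
    )
    return mapping.sort_index()


def restrict_samples(
    samples: pd.DataFrame, gm_mask: ActivityMap | None = None
) -> pd.Index:
    """Left-hemisphere cortical samples inside the gray-matter mask.

    Mask lookup is nearest-voxel; coordinates outside the mask volume's
    bounding box are dropped with a logged count.
    """
    keep = (samples["hemisphere"] == "L") & (samples["tissue_class"] == "cortex")
    if gm_mask is not None:
        coords = samples[["mni_x", "mni_y", "mni_z"]].to_numpy(float)
        vox = np.rint(mm_to_voxel(coords, gm_mask.affine)).astype(int)
        shape = np.array(gm_mask.data.shape)
        inside = ((vox >= 0) & (vox < shape)).all(axis=1)
        n_oob = int((keep & ~inside).sum())
        if n_oob:
            logger.info("sample restriction: %d sample(s) outside mask volume dropped", n_oob)
        in_gm = np.zeros(len(samples), bool)
        iv = vox[inside]
        in_gm[inside] = gm_mask.data[iv[:, 0], iv[:, 1], iv[:, 2]] > 0
        keep &= inside & in_gm
    kept = samples.index[keep]
    logger.info("sample restriction: kept %d / %d samples", len(kept), len(samples))
    return kept


def _srs_array(x: np.ndarray) -> np.ndarray:
    """SRS down axis 0 of a 2D array, vectorized over columns."""
    med = np.median(x, axis=0, keepdims=True)
    q75, q25 = np.percentile(x, [75, 25], axis=0, keepdims=True)
    iqr = q75 - q25
    degenerate = iqr[0] == 0
    if degenerate.any():
        logger.debug("SRS: %d zero-IQR vector(s) set to constant 0.5", int(degenerate.sum()))
    scale = np.where(iqr == 0, 1.0, iqr / IQR_NORMAL_CONSISTENCY)
    s = 1.0 / (1.0 + np.exp(-(x - med) / scale))
    lo = s.min(axis=0, keepdims=True)
    hi = s.max(axis=0, keepdims=True)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    out = (s - lo) / span
    out[:, degenerate] = 0.5
    return out


def srs_normalize(matrix: pd.DataFrame, axis: int = 0) -> pd.DataFrame:
    """Scaled robust sigmoid along ``axis`` (0 = down columns, 1 = across rows).

    Each vector x is mapped through a sigmoid centred at its median and
    scaled by IQR / 1.35 (normal-consistent spread), then min-max rescaled
    to [0, 1].  The transform is strictly monotone, so within-vector rank
    order is preserved; zero-IQR vectors map to constant 0.5.
    """
    vals = matrix.to_numpy(float)
    if axis == 0:
        out = _srs_array(vals)
    elif axis == 1:
        out = _srs_array(vals.T).T
    else:
        raise ValueError("axis must be 0 or 1")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def srs_normalize_per_donor(matrix: pd.DataFrame, donors: pd.Series) -> pd.DataFrame:
    """Two-stage SRS within each donor: cross-gene per sample, then
    cross-sample per gene."""
    parts = []
    for donor in pd.unique(donors):
        sub = matrix.loc[donors[donors == donor].index]
        sub = srs_normalize(sub, axis=1)   # within-sample across genes
        sub = srs_normalize(sub, axis=0)   # within-gene across samples
        parts.append(sub)
    return pd.concat(parts).loc[matrix.index]


def differential_stability(
    matrices: dict[str, pd.DataFrame],
    structures: dict[str, pd.Series],
    min_shared: int = 3,
) -> pd.Series:
    """Per-gene differential stability across donors.

    For each donor, expression is averaged within structure; for each donor
    pair sharing at least ``min_shared`` structures, the Spearman
    correlation between the two structure-mean vectors is computed per
    gene; DS is the mean over valid pairs.

    Parameters
    ----------
    matrices : donor -> (samples x genes) DataFrame (shared gene columns).
    structures : donor -> per-sample structure labels (aligned with rows).
    """
    donors = list(matrices)
    if len(donors) < 2:
        raise ValueError("differential stability needs at least 2 donors")
    genes = matrices[donors[0]].columns
    struct_means = {
        d: matrices[d].groupby(structures[d].to_numpy()).mean() for d in donors
    }
    acc = np.zeros(len(genes))
    n_pairs = 0
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            a, b = struct_means[donors[i]], struct_means[donors[j]]
            shared = a.index.intersection(b.index)
            if len(shared) < min_shared:
                logger.info(
                    "DS: donor pair (%s, %s) shares %d structures; skipped",
                    donors[i], donors[j], len(shared),
                )
                continue
            ra = rankdata(a.loc[shared].to_numpy(), axis=0)
            rb = rankdata(b.loc[shared].to_numpy(), axis=0)
            ra = ra - ra.mean(axis=0)
            rb = rb - rb.mean(axis=0)
            num = (ra * rb).sum(axis=0)
            den = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            acc += rho
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no donor pair shares enough structures for DS")
    return pd.Series(acc / n_pairs, index=genes, name="ds")


def select_top_ds(ds: pd.Series, fraction: float = 0.5) -> pd.Index:
    """Genes with DS at or above the (1 - fraction) quantile; ties retained."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    cut = ds.quantile(1.0 - fraction)
    return ds.index[ds >= cut]


def process_expression_bundle(
    bundle: ExpressionBundle,
    gm_mask: ActivityMap | None = None,
    min_prop: float = 0.5,
    min_r: float = 0.2,
    ds_fraction: float = 0.5,
) -> GeneExpressionMatrix:
    """Run the full expression pipeline on a bundle.

    Order: probe intensity filtering -> RNA-seq probe selection -> sample
    restriction -> per-donor SRS normalization -> DS computation and
    top-fraction gene retention.
    """
    kept_probes = filter_probes_intensity(bundle.expression, bundle.noise_flags, min_prop)
    probes = bundle.probes.loc[bundle.probes.index.intersection(kept_probes)]
    expression = bundle.expression.loc[probes.index]

    gene_probe = select_probes_by_rnaseq(probes, expression, bundle.rnaseq, bundle.samples, min_r)

    kept_samples = restrict_samples(bundle.samples, gm_mask)
    if len(kept_samples) == 0:
        raise ValueError("no samples survive restriction")

    # samples x genes matrix from the representative probes
    matrix = expression.loc[gene_probe.to_numpy(), kept_samples].T
    matrix.columns = gene_probe.index

    donors = bundle.samples.loc[kept_samples, "donor"].astype(str)
    norm = srs_normalize_per_donor(matrix, donors)

    per_donor = {d: norm.loc[donors[donors == d].index] for d in pd.unique(donors)}
    struct = {
        d: bundle.samples.loc[per_donor[d].index, "structure"].astype(str)
        for d in per_donor
    }
    ds = differential_stability(per_donor, struct)
    kept_genes = select_top_ds(ds, ds_fraction)

    annotations = bundle.samples.loc[kept_samples, ["donor", "mni_x", "mni_y", "mni_z", "hemisphere", "structure"]]
    return GeneExpressionMatrix(norm[kept_genes], annotations, ds.loc[kept_genes])
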