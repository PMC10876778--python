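"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover every input the analysis needs, so the whole
pipeline is exercisable without external data:

``generate_cohort``
    two groups of 4D BOLD-like volumes with per-subject motion traces and
    schematic tissue masks.  Voxel noise is temporally autocorrelated
    Gaussian (AR(1), phi = 0.3).  Every subject additionally carries a
    small set of spatially smooth latent components ("networks") whose
    voxel loadings have unit norm, so local temporal coherence is roughly
    uniform across the brain; the overall coupling amplitude varies from
    subject to subject, which is the between-subject baseline variability
    that global-mean standardization is meant to remove.  In one group,
    voxels inside a planted sphere additionally share a latent time
    series whose mixing weight is calibrated (pilot simulation, frozen
    table below) so the group difference in mean in-sphere ReHo
    approximates a requested Cohen's d.

``generate_expression_bundle``
    a donor microarray bundle (probe intensities, probe->gene annotations,
    above-background flags, RNA-seq reference, sample annotations) in which
    a chosen number of "tracking" genes follow a supplied target map across
    sample locations at a nominal correlation, each gene has a designated
    best probe, and decoy probes are either below background or
    uncorrelated with the RNA-seq reference.

``generate_clinical_table``
    a two-group clinical score table in which one designated scale (HAMA)
    is shifted between groups by a requested number of pooled SDs and all
    other scores are null.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .images import ActivityMap, StatMap, TimeSeriesVolume, sphere_mask, voxel_centers_mm

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "ExpressionBundleSpec",
    "SyntheticSubject",
    "SyntheticCohort",
    "generate_cohort",
    "generate_expression_bundle",
    "generate_clinical_table",
]

# --- fixed generator constants -------------------------------------------

AR_PHI = 0.3                 # temporal autocorrelation of voxel noise
N_LATENT = 12                # number of shared latent "network" components
LATENT_SMOOTH_VOX = 2.0      # spatial smoothness (voxels) of latent loadings
COUPLING = 0.5               # central coupling amplitude of the latent components
COUPLING_SPREAD = 0.35       # bounded relative between-subject spread (via tanh)
MOTION_STEP_TRANS_MM = 0.025
MOTION_STEP_ROT_RAD = 0.0005
MOTION_SPIKE_PROB = 0.02     # per-volume probability of a large jump
BASELINE = 1000.0
DRIFT_SD = 2.0               # per-voxel linear drift amplitude over the scan
MOTION_ARTIFACT_SD = 0.15    # per-voxel coupling of motion params into signal
GRID_CENTER_MM = (0.0, 10.0, -10.0)  # field-of-view centre (covers orbitofrontal cortex)

# Mixing weight of the planted shared component as a function of the
# requested Cohen's d of the in-sphere mean-ReHo group difference.
# Calibrated once by pilot simulation (120 subjects per weight, 20^3 grid,
# 240 volumes, 7.5-mm sphere) under the default noise constants; the
# fitted response d(w) = 10.68 w^2 / (3.00 + w^2) (valid to d = 2.5) was
# inverted onto this grid.  See docs/methods.md.  Interpolated linearly.
_EFFECT_D_GRID = np.array([0.0, 0.2, 0.4, 0.6, 0.754, 1.0, 1.2, 1.5, 2.0, 2.5])
_EFFECT_W_GRID = np.array([0.0, 0.239, 0.342, 0.423, 0.477, 0.557, 0.616, 0.700, 0.832, 0.958])


def _effect_weight(d: float) -> float:
    if d < 0:
        raise ValueError("planted_effect_d must be nonnegative")
    if d > _EFFECT_D_GRID[-1]:
        raise ValueError(f"planted_effect_d={d} beyond calibrated range {_EFFECT_D_GRID[-1]}")
    return float(np.interp(d, _EFFECT_D_GRID, _EFFECT_W_GRID))


@dataclass
class CohortSpec:
    """Conditions for a two-group resting-state cohort.

    ``n_per_group`` may be a single count or an ``(n_a, n_b)`` pair;
    defaults emulate a 30-control / 27-patient study scanned at TR = 2 s
    for 240 volumes, with the planted coherence increase centred in left
    orbitofrontal cortex at an effect size of d = 0.754.
    """

    n_per_group: int | tuple[int, int] = (30, 27)
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 3.0
    n_volumes: int = 240
    tr_seconds: float = 2.0
    planted_center_mm: tuple[float, float, float] = (-9.0, 36.0, -27.0)
    planted_radius_mm: float = 7.5
    planted_effect_d: float = 0.754
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, (int, np.integer)):
            self.n_per_group = (int(self.n_per_group), int(self.n_per_group))
        self.n_per_group = tuple(int(n) for n in self.n_per_group)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.planted_center_mm = tuple(float(c) for c in self.planted_center_mm)
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.planted_radius_mm <= 0:
            raise ValueError("planted_radius_mm must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")

    @property
    def affine(self) -> np.ndarray:
        v = self.voxel_size_mm
        shape = np.asarray(self.grid_shape)
        origin = np.asarray(GRID_CENTER_MM) - v * (shape - 1) / 2.0
        aff = np.diag([v, v, v, 1.0])
        aff[:3, 3] = origin
        return aff


@dataclass
class SyntheticSubject:
    volume: TimeSeriesVolume
    motion: np.ndarray  # (t, 6)


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    group_a: list[SyntheticSubject]
    group_b: list[SyntheticSubject]
    affine: np.ndarray
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    planted_mask: np.ndarray

    def gm_map(self) -> ActivityMap:
        return ActivityMap(self.gm_mask.astype(float), self.affine, "gm_mask")


def _tissue_masks(spec: CohortSpec) -> tuple[np.ndarray, ...]:
    """Schematic tissue geometry: a superellipsoid brain with a small
    central CSF core and a WM shell around it; GM is the remainder."""
    shape = spec.grid_shape
    centers = voxel_centers_mm(shape, spec.affine).reshape(*shape, 3)
    rel = centers - np.asarray(GRID_CENTER_MM)
    half = spec.voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    semi = 0.95 * half
    s4 = ((rel / semi) ** 4).sum(axis=-1) ** 0.25
    brain = s4 <= 1.0
    dist = np.sqrt((rel**2).sum(axis=-1))
    csf = brain & (dist <= 2.0 * spec.voxel_size_mm)
    wm = brain & (dist > 2.0 * spec.voxel_size_mm) & (dist <= 4.5 * spec.voxel_size_mm)
    gm = brain & ~csf & ~wm
    return brain, gm, wm, csf


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float = AR_PHI) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis."""
    n = shape[-1]
    burn = 25
    e = rng.standard_normal(shape[:-1] + (n + burn,))
    x = lfilter([1.0], [1.0, -phi], e, axis=-1)[..., burn:]
    return x * np.sqrt(1.0 - phi**2)


def _motion_trace(rng: np.random.Generator, n: int) -> np.ndarray:
    steps = np.empty((n, 6))
    steps[:, :3] = rng.standard_normal((n, 3)) * MOTION_STEP_TRANS_MM
    steps[:, 3:] = rng.standard_normal((n, 3)) * MOTION_STEP_ROT_RAD
    spikes = rng.random(n) < MOTION_SPIKE_PROB
    steps[spikes, :3] += rng.standard_normal((int(spikes.sum()), 3)) * 0.4
    steps[0] = 0.0
    kernel = np.array([0.25, 0.5, 0.25])
    for j in range(6):
        steps[:, j] = np.convolve(steps[:, j], kernel, mode="same")
    return np.cumsum(steps, axis=0)


def _subject_volume(
    rng: np.random.Generator,
    spec: CohortSpec,
    brain: np.ndarray,
    planted: np.ndarray | None,
    weight: float,
) -> SyntheticSubject:
    shape = spec.grid_shape
    n = spec.n_volumes
    data = _ar1(rng, shape + (n,))
    data[~brain] *= 0.1

    # shared latent components with unit-norm smooth loadings: local
    # coherence is near-uniform in space, its amplitude subject-specific;
    # tanh bounds the spread so small-sample SD estimates stay stable
    amp = COUPLING * (1.0 + COUPLING_SPREAD * np.tanh(rng.standard_normal()))
    f = _ar1(rng, (N_LATENT, n))
    h = gaussian_filter(
        rng.standard_normal((N_LATENT, *shape)),
        sigma=(0, LATENT_SMOOTH_VOX, LATENT_SMOOTH_VOX, LATENT_SMOOTH_VOX),
    )
    h /= np.sqrt((h**2).sum(axis=0, keepdims=True)) + 1e-12
    data[brain] += amp * (h[:, brain].T @ f)

    if planted is not None and weight > 0:
        s = _ar1(rng, (n,))
        data[planted] += weight * s

    motion = _motion_trace(rng, n)
    mstd = (motion - motion.mean(axis=0)) / (motion.std(axis=0) + 1e-12)
    coupling = rng.standard_normal((*shape, 6)) * MOTION_ARTIFACT_SD
    data[brain] += (coupling[brain] @ mstd.T)

    drift = rng.standard_normal(shape) * DRIFT_SD
    ramp = np.linspace(-0.5, 0.5, n)
    data += BASELINE + drift[..., None] * ramp

    vol = TimeSeriesVolume(data, spec.affine, spec.tr_seconds)
    return SyntheticSubject(vol, motion)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate both groups of a cohort from a :class:`CohortSpec`.

    Group A is the control group; group B carries the planted coherence
    increase.  Raises if the planted sphere does not fit inside the grid.
    """
    affine = spec.affine
    brain, gm, wm, csf = _tissue_masks(spec)

    center = np.asarray(spec.planted_center_mm, float)
    half = spec.voxel_size_mm * (np.asarray(spec.grid_shape) - 1) / 2.0
    lo = np.asarray(GRID_CENTER_MM) - half
    hi = np.asarray(GRID_CENTER_MM) + half
    if ((center - spec.planted_radius_mm) < lo).any() or ((center + spec.planted_radius_mm) > hi).any():
        raise ValueError(
            f"planted sphere at {tuple(center)} (radius {spec.planted_radius_mm} mm) "
            f"extends outside the grid [{tuple(lo)}, {tuple(hi)}]"
        )
    planted = sphere_mask(spec.grid_shape, affine, center, spec.planted_radius_mm)
    if not (planted & gm).any():
        raise ValueError(
            f"planted sphere at {tuple(center)} contains no gray-matter voxel"
        )

    weight = _effect_weight(spec.planted_effect_d)
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.n_per_group
    group_a = [_subject_volume(rng, spec, brain, None, 0.0) for _ in range(n_a)]
    group_b = [
        _subject_volume(rng, spec, brain, planted if weight > 0 else None, weight)
        for _ in range(n_b)
    ]
    return SyntheticCohort(spec, group_a, group_b, affine, brain, gm, wm, csf, planted)


# --- expression bundle ----------------------------------------------------

@dataclass
class ExpressionBundleSpec:
    """Conditions for a donor microarray bundle.

    Defaults emulate a six-donor atlas reduced to the post-filtering gene
    count of the analysis (5,013 genes).  ``n_tracking_genes`` genes follow
    the supplied target map at a nominal cross-sample correlation
    ``tracking_r``; the remainder are spatially unstructured.
    """

    n_donors: int = 6
    n_samples_per_donor: int = 70
    n_probes: int = 7520
    n_genes: int = 5013
    n_tracking_genes: int = 0
    tracking_r: float = 0.6
    seed: int = 0
    # fractions of per-donor samples generated as restriction decoys
    frac_right: float = 0.08
    frac_subcortical: float = 0.10
    n_structures: int = 10
    frac_genes_missing_rnaseq: float = 0.03

    def __post_init__(self) -> None:
        if self.n_probes < self.n_genes:
            raise ValueError("need at least one probe per gene (n_probes >= n_genes)")
        if not 0 <= self.n_tracking_genes <= self.n_genes:
            raise ValueError(
                f"n_tracking_genes={self.n_tracking_genes} must be in [0, n_genes={self.n_genes}]"
            )
        if abs(self.tracking_r) > 1:
            raise ValueError("|tracking_r| must be <= 1")
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")


@dataclass
class BundleTruth:
    """Ground truth of a generated bundle, for exactness checks."""

    tracking_genes: list[str]
    best_probe: pd.Series          # gene -> designated best probe id
    left_cortex_samples: pd.Index  # samples that should survive restriction
    target_at_samples: np.ndarray  # target-map value at every sample


def _structure_labels(coords: np.ndarray, edges_y: np.ndarray, n_z: int, z_edges: np.ndarray) -> list[str]:
    iy = np.clip(np.searchsorted(edges_y, coords[:, 1], side="right") - 1, 0, len(edges_y) - 2)
    iz = np.clip(np.searchsorted(z_edges, coords[:, 2], side="right") - 1, 0, n_z - 1)
    return [f"CTX{int(a) * n_z + int(b) + 1:02d}" for a, b in zip(iy, iz)]


def generate_expression_bundle(
    spec: ExpressionBundleSpec,
    target_map: StatMap,
    mask: np.ndarray | None = None,
):
    """Generate a donor expression bundle tied to a target map.

    Sample coordinates are drawn uniformly from in-mask voxel centres in
    the left hemisphere (x < 0 in MNI mm); a small fraction of decoy
    samples are mirrored to the right hemisphere or labelled subcortical.
    Tracking genes' per-sample signal is ``r * z(target) + sqrt(1-r^2) *
    noise``.  Each gene's designated best probe carries the gene signal
    with low measurement noise; decoy probes are either below background
    or spatially uncorrelated with the RNA-seq reference, so probe
    selection has a unique correct answer.

    Returns ``(bundle, truth)``.
    """
    from .expression import ExpressionBundle  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    if mask is None:
        mask = target_map.data != 0
    mask = np.asarray(mask, bool)

    centers = voxel_centers_mm(target_map.data.shape, target_map.affine)
    flat_mask = mask.ravel()
    left = flat_mask & (centers[:, 0] < 0)
    left_idx = np.flatnonzero(left)
    if left_idx.size == 0:
        raise ValueError("mask has no left-hemisphere (x < 0) voxels")
    left_centers = centers[left_idx]
    left_values = target_map.data.ravel()[left_idx]

    # deterministic cortical parcellation of the left in-mask volume
    n_z = 2
    n_y = spec.n_structures // n_z
    edges_y = np.quantile(left_centers[:, 1], np.linspace(0, 1, n_y + 1))
    edges_y[0] -= 1.0
    edges_y[-1] += 1.0
    z_edges = np.quantile(left_centers[:, 2], np.linspace(0, 1, n_z + 1))[:-1]
    z_edges[0] -= 1.0

    n_per = spec.n_samples_per_donor
    n_right = int(round(spec.frac_right * n_per))
    n_sub = int(round(spec.frac_subcortical * n_per))
    n_left = n_per - n_right - n_sub
    if n_left < spec.n_structures:
        raise ValueError("too few left-cortex samples per donor for the parcellation")

    rows = []
    coords_all = []
    for d in range(spec.n_donors):
        donor = f"D{d + 1:02d}"
        pick = rng.choice(left_idx.size, n_left, replace=False)
        c_left = left_centers[pick]
        labels = _structure_labels(c_left, edges_y, n_z, z_edges)
        for c, lab in zip(c_left, labels):
            rows.append((donor, *c, "L", "cortex", lab))
            coords_all.append(c)
        pick_r = rng.choice(left_idx.size, n_right, replace=False)
        c_right = left_centers[pick_r] * np.array([-1.0, 1.0, 1.0])
        labels_r = _structure_labels(c_right, edges_y, n_z, z_edges)
        for c, lab in zip(c_right, labels_r):
            rows.append((donor, *c, "R", "cortex", lab))
            coords_all.append(c)
        jitter = rng.standard_normal((n_sub, 3)) * 4.0
        for c in np.asarray(GRID_CENTER_MM) + jitter:
            rows.append((donor, *c, "L", "subcortex", "SUBCTX"))
            coords_all.append(c)

    samples = pd.DataFrame(
        rows, columns=["donor", "mni_x", "mni_y", "mni_z", "hemisphere", "tissue_class", "structure"]
    )
    samples.index = pd.Index([f"S{i + 1:05d}" for i in range(len(samples))], name="sample")
    coords_all = np.asarray(coords_all)

    # target value at each sample's nearest voxel (0 outside the grid)
    inv = np.linalg.inv(target_map.affine)
    vox = np.rint((inv[:3, :3] @ coords_all.T).T + inv[:3, 3]).astype(int)
    shape = np.asarray(target_map.data.shape)
    inside = ((vox >= 0) & (vox < shape)).all(axis=1)
    tau = np.zeros(len(samples))
    tau[inside] = target_map.data[vox[inside, 0], vox[inside, 1], vox[inside, 2]]
    tau_z = (tau - tau.mean()) / (tau.std() + 1e-12)

    gene_names = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]
    tracking = gene_names[: spec.n_tracking_genes]

    r = spec.tracking_r
    n_s = len(samples)
    signal = rng.standard_normal((spec.n_genes, n_s))
    if tracking:
        signal[: spec.n_tracking_genes] = (
            r * tau_z + np.sqrt(max(0.0, 1.0 - r**2)) * signal[: spec.n_tracking_genes]
        )

    # floor keeps every designated best probe above the per-donor background
    # threshold, so probe selection has a unique correct answer
    baseline = np.maximum(6.5, 8.0 + 1.5 * rng.standard_normal(spec.n_genes))
    baseline[: spec.n_tracking_genes] = np.maximum(baseline[: spec.n_tracking_genes], 8.0)

    # probes: one designated best probe per gene, then decoys
    probe_gene: list[int] = list(range(spec.n_genes))
    n_extra = spec.n_probes - spec.n_genes
    probe_gene += list(rng.integers(0, spec.n_genes, n_extra))
    probe_ids = [f"P{i + 1:06d}" for i in range(spec.n_probes)]
    decoy_kind = rng.random(n_extra)  # < 0.4 -> below background, else uncorrelated

    intensity = np.empty((spec.n_probes, n_s))
    for j in range(spec.n_genes):
        intensity[j] = baseline[j] + signal[j] + 0.25 * rng.standard_normal(n_s)
    for k in range(n_extra):
        j = spec.n_genes + k
        g = probe_gene[j]
        if decoy_kind[k] < 0.4:
            intensity[j] = 3.0 + 0.5 * rng.standard_normal(n_s)
        else:
            intensity[j] = baseline[g] + rng.standard_normal(n_s) + 0.25 * rng.standard_normal(n_s)

    probes = pd.DataFrame(
        {"gene": [gene_names[g] for g in probe_gene]},
        index=pd.Index(probe_ids, name="probe"),
    )
    expression = pd.DataFrame(intensity, index=probes.index, columns=samples.index)

    # above-background flags: per-donor 0.2-quantile intensity threshold
    flags = pd.DataFrame(False, index=probes.index, columns=samples.index)
    for donor, sub in samples.groupby("donor"):
        block = expression[sub.index].to_numpy()
        thr = np.quantile(block, 0.2)
        flags[sub.index] = block > thr
    flags = flags.astype(bool)

    # RNA-seq reference: per (donor, structure) structure-mean gene signal
    keys = (samples["donor"] + "|" + samples["structure"]).to_numpy()
    sig_df = pd.DataFrame(signal.T, index=samples.index, columns=gene_names)
    struct_mean = sig_df.groupby(keys).mean().T  # genes x keys
    rnaseq = struct_mean + 0.3 * rng.standard_normal(struct_mean.shape)
    n_missing = int(round(spec.frac_genes_missing_rnaseq * spec.n_genes))
    if n_missing:
        # drop only non-tracking genes from the RNA-seq platform
        droppable = np.array(gene_names[spec.n_tracking_genes:])
        drop = rng.choice(droppable, n_missing, replace=False)
        rnaseq = rnaseq.drop(index=drop)
    rnaseq.index.name = "gene"

    samples_out = samples.copy()
    bundle = ExpressionBundle(probes, expression, flags, rnaseq, samples_out)
    truth = BundleTruth(
        tracking_genes=tracking,
        best_probe=pd.Series(
            {gene_names[g]: probe_ids[g] for g in range(spec.n_genes)}, name="probe"
        ),
        left_cortex_samples=samples.index[
            (samples["hemisphere"] == "L") & (samples["tissue_class"] == "cortex")
        ],
        target_at_samples=tau,
    )
    return bundle, truth


# --- clinical table -------------------------------------------------------

# (mean, sd) per scale, loosely matched to an episodic-migraine cohort
_CLINICAL_SCALES = {
    "age": (33.0, 8.0),
    "education_years": (15.0, 3.0),
    "bmi": (22.2, 3.0),
    "fd_mm": (0.12, 0.05),
    "hama": (5.0, 5.0),
    "bdi": (5.0, 4.5),
    "duration_years": (9.0, 6.0),
    "vas": (6.4, 1.8),
    "hit6": (61.0, 6.0),
    "moca": (26.5, 2.0),
    "bfi_neuroticism": (31.5, 7.0),
}
SHIFTED_SCALE = "hama"


def generate_clinical_table(
    n_a: int = 30, n_b: int = 27, score_shift: float = 1.4, seed: int = 0
) -> pd.DataFrame:
    """Two-group clinical table; groups HC (A) and EM (B).

    The designated scale (HAMA) differs between groups by ``score_shift``
    pooled standard deviations; every other score is drawn from the same
    distribution in both groups.  Sex is drawn with the same female-heavy
    proportion in both groups.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    out = pd.DataFrame({"group": ["HC"] * n_a + ["EM"] * n_b})
    out["sex"] = np.where(rng.random(n) < 0.88, "F", "M")
    for scale, (mu, sd) in _CLINICAL_SCALES.items():
        vals = mu + sd * rng.standard_normal(n)
        if scale == SHIFTED_SCALE:
            vals[n_a:] += score_shift * sd
        out[scale] = vals
    out.index = pd.Index([f"sub{i + 1:03d}" for i in range(n)], name="subject")
    return out
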