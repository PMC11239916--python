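"""Synthetic cohorts of ROI time series and demographics.

Generates the inputs the downstream pipeline expects: per-subject ROI
time series drawn from a stationary multivariate normal with modular
covariance (ROI families such as frontal, sensorimotor, cerebellum ...),
plus a cohort table of group, sex, age, BMI and mJOA. Group-, sex- and
cell-specific effects are injected as known perturbations of selected
edges or of whole-module connectivity, and the realized population
structure is recorded so recovery can be scored against ground truth.

The signal model is second-order only (no hemodynamic convolution):
every statistic computed downstream — correlations, edge-wise GLMs,
graph metrics — depends only on the covariance of the signals.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .connectivity import ROITimeSeries

logger = logging.getLogger(__name__)

GROUPS = ("patient", "control")
SEXES = ("M", "F")
#: All four cohort cells, in canonical order.
CELLS = tuple((g, s) for g in GROUPS for s in SEXES)

#: Maximum allowed element-wise change introduced by the PSD repair
#: before a design is rejected as invalid.
PSD_REPAIR_TOLERANCE = 0.1

#: Healthy neurological status pins the mJOA score at its ceiling.
MJOA_MAX = 18
FULL_MJOA = MJOA_MAX


class DesignError(ValueError):
    """Raised when a cohort design cannot produce a valid population."""


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort table."""

    subject_id: str
    group: str  # 'patient' | 'control'
    sex: str  # 'M' | 'F'
    age: float  # years
    bmi: float  # kg/m^2
    mjoa: int  # 0..18; controls are 18 by definition

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DesignError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise DesignError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0 <= self.mjoa <= MJOA_MAX:
            raise DesignError(f"mjoa must be in [0, {MJOA_MAX}], got {self.mjoa}")
        if self.group == "control" and self.mjoa != FULL_MJOA:
            raise DesignError(
                f"control subjects carry mjoa={FULL_MJOA} by definition, "
                f"got {self.mjoa} for {self.subject_id}"
            )
        if not 18 <= self.age <= 85:
            raise DesignError(f"age must be in [18, 85] years, got {self.age}")

    @property
    def cell(self) -> tuple[str, str]:
        return (self.group, self.sex)


@dataclass(frozen=True)
class EdgeEffect:
    """An injected shift of one edge's population correlation.

    ``group``/``sex`` restrict which cohort cells receive the shift;
    ``None`` matches everything (so ``group='patient', sex=None``
    perturbs both patient cells).
    """

    roi_i: str
    roi_j: str
    delta_r: float
    group: str | None = None
    sex: str | None = None

    def matches(self, cell: tuple[str, str]) -> bool:
        return (self.group is None or self.group == cell[0]) and (
            self.sex is None or self.sex == cell[1]
        )


@dataclass(frozen=True)
class CovariateSlope:
    """A per-edge linear dependence of correlation on a covariate.

    The edge's population correlation shifts by
    ``slope * (value - cell mean) / cell sd`` for each subject, so the
    edge-wise GLM's covariate adjustment has real structure to remove.
    """

    roi_i: str
    roi_j: str
    variable: str  # 'age' | 'bmi'
    slope: float  # correlation shift per covariate SD


@dataclass(frozen=True)
class DemographicCell:
    """Truncated-normal parameters for one cohort cell's covariates."""

    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    bmi_mean: float
    bmi_sd: float
    bmi_range: tuple[float, float]
    mjoa_mean: float = float(FULL_MJOA)
    mjoa_sd: float = 0.0
    mjoa_range: tuple[int, int] = (FULL_MJOA, FULL_MJOA)


def _default_covariate_model() -> dict[tuple[str, str], DemographicCell]:
    """Study-like demographics per cell.

    Patients: ages 31-81 (means ~58/57 by sex), BMI 18.9-41.0, mJOA
    10-18 with means ~15.3/15.8. Controls: ages 45-73 (means ~50),
    BMI 19.2-40.7, mJOA pinned at 18.
    """
    return {
        ("patient", "M"): DemographicCell(58.1, 11.5, (31, 81), 26.2, 3.9,
                                          (18.9, 41.0), 15.3, 2.5, (10, 18)),
        ("patient", "F"): DemographicCell(57.3, 11.0, (31, 81), 26.1, 5.0,
                                          (18.9, 41.0), 15.8, 2.2, (10, 18)),
        ("control", "M"): DemographicCell(50.4, 5.0, (45, 73), 27.1, 4.3,
                                          (19.2, 40.7)),
        ("control", "F"): DemographicCell(49.6, 3.5, (45, 73), 26.3, 5.2,
                                          (19.2, 40.7)),
    }


#: Canonical ROI families (anatomical groupings of the parcellation).
DEFAULT_MODULES = (
    "frontal",
    "sensorimotor",
    "parietal",
    "thalamus_basal_ganglia",
    "cingulate",
    "occipital_visual",
    "cerebellum",
    "brainstem",
)


def default_parcellation(n_rois: int = 132) -> tuple[list[str], dict[str, str]]:
    """ROI labels and module assignment for a synthetic parcellation.

    ROIs are spread over the eight canonical families roughly in
    proportion to a whole-brain atlas (the cerebellum is the largest
    family, the brainstem the smallest).
    """
    if n_rois < len(DEFAULT_MODULES):
        raise DesignError(
            f"need at least {len(DEFAULT_MODULES)} ROIs for the default "
            f"parcellation, got {n_rois}"
        )
    # Relative family sizes; brainstem is a single region in the atlas.
    shares = {
        "frontal": 5, "sensorimotor": 6, "parietal": 5,
        "thalamus_basal_ganglia": 4, "cingulate": 2,
        "occipital_visual": 6, "cerebellum": 8, "brainstem": 1,
    }
    total = sum(shares.values())
    counts = {m: max(1, int(round(n_rois * shares[m] / total)))
              for m in DEFAULT_MODULES}
    # Adjust the largest family so counts sum exactly to n_rois.
    drift = n_rois - sum(counts.values())
    counts["cerebellum"] = max(1, counts["cerebellum"] + drift)
    labels: list[str] = []
    partition: dict[str, str] = {}
    for module in DEFAULT_MODULES:
        for i in range(counts[module]):
            label = f"{module}_{i + 1:02d}"
            labels.append(label)
            partition[label] = module
    return labels, partition


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    roi_labels : list of str
        Unique ROI names (length N).
    module_partition : dict
        ROI label -> module (family) name.
    n_per_cell : dict
        (group, sex) -> subject count; every listed cell needs >= 2.
    series_length : int
        Samples per subject (T).
    sampling_interval : float
        TR in seconds.
    base_within_r, base_between_r : float
        Population correlation for ROI pairs in the same / different
        modules, before any injected effect.
    edge_effects : list of EdgeEffect
        Per-edge correlation shifts, optionally cell-restricted.
    topology_effects : dict
        (group, sex) -> additive within-module correlation increment;
        models a global topology difference for that cell.
    covariate_model : dict
        (group, sex) -> DemographicCell. Defaults to study-like values.
    noise_sd : float
        SD of white observation noise added to the unit-variance
        signals; shrinks observable correlations by 1/(1 + noise_sd^2).
    seed : int
        Master seed; per-subject substreams are derived by stable
        hashing of the subject id.
    """

    roi_labels: list[str]
    module_partition: dict[str, str]
    n_per_cell: dict[tuple[str, str], int]
    series_length: int = 200
    sampling_interval: float = 2.0
    base_within_r: float = 0.5
    base_between_r: float = 0.1
    edge_effects: list[EdgeEffect] = field(default_factory=list)
    topology_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    covariate_slopes: list[CovariateSlope] = field(default_factory=list)
    covariate_model: dict[tuple[str, str], DemographicCell] = field(
        default_factory=_default_covariate_model
    )
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.roi_labels)
        if len(set(self.roi_labels)) != n:
            raise DesignError("ROI labels must be unique")
        missing = [r for r in self.roi_labels if r not in self.module_partition]
        if missing:
            raise DesignError(f"ROIs missing from module_partition: {missing[:5]}")
        for cell, count in self.n_per_cell.items():
            if cell not in CELLS:
                raise DesignError(f"unknown cohort cell {cell}")
            if count < 2:
                raise DesignError(f"cell {cell} needs n >= 2, got {count}")
        if not -1 < self.base_between_r < 1 or not 0 <= self.base_within_r < 1:
            raise DesignError("base correlations must lie in (-1, 1)")
        for eff in self.edge_effects:
            for roi in (eff.roi_i, eff.roi_j):
                if roi not in self.roi_labels:
                    raise DesignError(f"edge effect names unknown ROI {roi!r}")
            if eff.roi_i == eff.roi_j:
                raise DesignError("edge effect must join two distinct ROIs")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be nonnegative")
        for cs in self.covariate_slopes:
            if cs.variable not in ("age", "bmi"):
                raise DesignError(
                    f"covariate slope on unknown variable {cs.variable!r}"
                )
            for roi in (cs.roi_i, cs.roi_j):
                if roi not in self.roi_labels:
                    raise DesignError(f"covariate slope names unknown ROI {roi!r}")
        if self.series_length < 10:
            raise DesignError("series_length must be at least 10")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def cells(self) -> list[tuple[str, str]]:
        return [c for c in CELLS if self.n_per_cell.get(c, 0) > 0]

    def roi_index(self, label: str) -> int:
        return self.roi_labels.index(label)


@dataclass
class CohortTruth:
    """Ground truth realized by a generated cohort."""

    population_correlation: dict[tuple[str, str], np.ndarray]
    perturbed_edges: list[EdgeEffect]


@dataclass
class SyntheticCohort:
    """Records, per-subject series, and the generating truth."""

    records: list[SubjectRecord]
    series: dict[str, ROITimeSeries]
    truth: CohortTruth
    design: CohortDesign

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate subject_id in cohort")
        if set(ids) != set(self.series):
            raise DesignError("records and series do not match one-to-one")


# ---------------------------------------------------------------------------
# Population structure


def nearest_psd(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Repair a symmetric matrix to PSD with unit diagonal.

    Negative eigenvalues are clipped at zero and the result is
    re-normalized to a correlation matrix. Returns the repaired matrix
    and the largest element-wise change the repair introduced.
    """
    sym = (matrix + matrix.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    if eigval[0] >= -1e-10:
        out = sym.copy()
        np.fill_diagonal(out, 1.0)
        return out, 0.0
    clipped = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    d = np.sqrt(np.diag(clipped))
    if np.any(d <= 0):
        raise DesignError("PSD repair produced a degenerate (zero-variance) ROI")
    out = clipped / np.outer(d, d)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out, float(np.max(np.abs(out - sym)))


def build_population_correlation(
    design: CohortDesign, cell: tuple[str, str]
) -> np.ndarray:
    """Population correlation matrix for one cohort cell.

    Entry (i, j) is ``base_within_r`` (plus the cell's topology
    increment) when i and j share a module, ``base_between_r``
    otherwise, plus ``delta_r`` for every edge effect matching the cell.
    Non-PSD results are repaired by eigenvalue clipping; a repair that
    moves any entry by more than ``PSD_REPAIR_TOLERANCE`` invalidates
    the design.
    """
    if design.n_per_cell.get(cell, 0) <= 0:
        raise DesignError(f"cell {cell} is not present in the design")
    n = design.n_rois
    modules = np.array(
        [design.module_partition[r] for r in design.roi_labels], dtype=object
    )
    same_module = modules[:, None] == modules[None, :]
    within = design.base_within_r + design.topology_effects.get(cell, 0.0)
    corr = np.where(same_module, within, design.base_between_r).astype(float)
    for eff in design.edge_effects:
        if not eff.matches(cell):
            continue
        i, j = design.roi_index(eff.roi_i), design.roi_index(eff.roi_j)
        corr[i, j] += eff.delta_r
        corr[j, i] += eff.delta_r
    np.fill_diagonal(corr, 1.0)
    off = corr[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise DesignError(
            f"cell {cell}: injected effects push |r| >= 1 "
            f"(max {np.max(np.abs(off)):.3f})"
        )
    repaired, change = nearest_psd(corr)
    if change > PSD_REPAIR_TOLERANCE:
        raise DesignError(
            f"cell {cell}: PSD repair would change correlations by "
            f"{change:.3f} > {PSD_REPAIR_TOLERANCE}"
        )
    if change > 0:
        logger.info("cell %s: PSD repair applied, max entry change %.2e",
                    cell, change)
    return repaired


def effective_correlation(corr: np.ndarray, noise_sd: float) -> np.ndarray:
    """Observable correlation after adding white noise of SD ``noise_sd``."""
    shrink = 1.0 / (1.0 + noise_sd**2)
    out = corr * shrink
    np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# Simulation


def simulate_subject(
    correlation: np.ndarray,
    n_samples: int,
    seed: int | np.random.SeedSequence,
    roi_labels: list[str] | None = None,
    subject_id: str = "sim",
    sampling_interval: float = 2.0,
    noise_sd: float = 0.0,
) -> ROITimeSeries:
    """Draw a T x N series from a zero-mean MVN with the given correlation.

    Deterministic for a fixed seed. White noise of SD ``noise_sd`` is
    added on top of the unit-variance latent signal, shrinking the
    observable correlations by ``1/(1 + noise_sd**2)``.
    """
    correlation = np.asarray(correlation, dtype=float)
    n = correlation.shape[0]
    if correlation.shape != (n, n):
        raise DesignError("correlation must be square")
    eigval, eigvec = np.linalg.eigh((correlation + correlation.T) / 2.0)
    if eigval[0] < -1e-8:
        raise DesignError(
            f"correlation is not PSD (min eigenvalue {eigval[0]:.2e})"
        )
    if n_samples < n:
        logger.warning(
            "T=%d < N=%d: sample correlation matrices will be rank deficient",
            n_samples, n,
        )
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_samples, n)) @ root.T
    if noise_sd > 0:
        latent = latent + noise_sd * rng.standard_normal((n_samples, n))
    if roi_labels is None:
        roi_labels = [f"roi_{i + 1:03d}" for i in range(n)]
    return ROITimeSeries(
        subject_id=subject_id,
        data=latent,
        roi_labels=list(roi_labels),
        sampling_interval=sampling_interval,
    )


def _subject_seed(master_seed: int, subject_id: str) -> np.random.SeedSequence:
    """Stable per-subject substream: master seed + CRC32 of the id.

    Adding or removing one subject never perturbs another subject's
    draw.
    """
    return np.random.SeedSequence([master_seed, zlib.crc32(subject_id.encode())])


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(_stats.norm.cdf(a), _stats.norm.cdf(b))
    return float(mean + sd * _stats.norm.ppf(u))


def _draw_record(
    rng: np.random.Generator, subject_id: str, cell: tuple[str, str],
    demo: DemographicCell,
) -> SubjectRecord:
    group, sex = cell
    age = _truncnorm(rng, demo.age_mean, demo.age_sd, *demo.age_range)
    bmi = _truncnorm(rng, demo.bmi_mean, demo.bmi_sd, *demo.bmi_range)
    if group == "control":
        mjoa = FULL_MJOA
    else:
        mjoa = int(round(_truncnorm(
            rng, demo.mjoa_mean, demo.mjoa_sd, *demo.mjoa_range
        )))
        mjoa = int(np.clip(mjoa, demo.mjoa_range[0], demo.mjoa_range[1]))
    return SubjectRecord(
        subject_id=subject_id, group=group, sex=sex,
        age=round(age, 1), bmi=round(bmi, 1), mjoa=mjoa,
    )


def _apply_covariate_slopes(
    corr: np.ndarray,
    design: CohortDesign,
    record: SubjectRecord,
    demo: DemographicCell,
) -> np.ndarray:
    """Shift selected edges by the subject's standardized covariates."""
    out = corr.copy()
    scale = {"age": (demo.age_mean, demo.age_sd),
             "bmi": (demo.bmi_mean, demo.bmi_sd)}
    for cs in design.covariate_slopes:
        mean, sd = scale[cs.variable]
        standardized = (getattr(record, cs.variable) - mean) / sd if sd > 0 else 0.0
        i, j = design.roi_index(cs.roi_i), design.roi_index(cs.roi_j)
        shift = cs.slope * standardized
        out[i, j] = np.clip(out[i, j] + shift, -0.99, 0.99)
        out[j, i] = out[i, j]
    repaired, _ = nearest_psd(out)
    return repaired


def generate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Generate the full cohort a design describes.

    Every subject gets an id ``<group>-<sex>-<index>``, demographics
    drawn from the design's covariate model, and a time series drawn
    from the cell's (noise-shrunk) population correlation. Fully
    reproducible from ``design.seed``.
    """
    records: list[SubjectRecord] = []
    series: dict[str, ROITimeSeries] = {}
    population: dict[tuple[str, str], np.ndarray] = {}
    for cell in design.cells:
        corr = build_population_correlation(design, cell)
        population[cell] = effective_correlation(corr, design.noise_sd)
        demo = design.covariate_model[cell]
        for idx in range(design.n_per_cell[cell]):
            subject_id = f"{cell[0]}-{cell[1]}-{idx + 1:03d}"
            seed_seq = _subject_seed(design.seed, subject_id)
            rng = np.random.default_rng(seed_seq)
            record = _draw_record(rng, subject_id, cell, demo)
            records.append(record)
            subject_corr = corr
            if design.covariate_slopes:
                subject_corr = _apply_covariate_slopes(
                    corr, design, record, demo
                )
            series[subject_id] = simulate_subject(
                subject_corr,
                design.series_length,
                seed_seq.spawn(1)[0],
                roi_labels=design.roi_labels,
                subject_id=subject_id,
                sampling_interval=design.sampling_interval,
                noise_sd=design.noise_sd,
            )
    active = [e for e in design.edge_effects
              if any(e.matches(c) for c in design.cells)]
    truth = CohortTruth(population_correlation=population, perturbed_edges=active)
    return SyntheticCohort(records=records, series=series, truth=truth,
                           design=design)
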