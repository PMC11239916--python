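"""File formats, run configuration, and the end-to-end pipeline.

Everything on disk is delimited text: CSV for the cohort table, TSV for
matrices, edge tables, topology curves and comparison tables, JSON or
YAML for configuration, JSON for the run manifest. Every output file
starts with a ``#`` comment line carrying the package version and the
run seed, and a manifest of SHA-256 checksums makes deterministic runs
verifiable byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CELLS,
    CohortDesign,
    DesignError,
    EdgeEffect,
    FULL_MJOA,
    SubjectRecord,
    default_parcellation,
    generate_cohort,
)
from .connectivity import (
    ConnectivityMatrix,
    DEFAULT_BANDPASS_HIGH_HZ,
    DEFAULT_BANDPASS_LOW_HZ,
    ROITimeSeries,
    preprocess_and_connect,
)
from .glm import DEFAULT_ALPHA_CONN, DEFAULT_ALPHA_FDR, fit_contrast
from .stats import (
    compare_demographics,
    compare_topology_auc,
    results_table,
    _select,
)
from .topology import DEFAULT_NULL_REPS, DEFAULT_TAUS, topology_curve

logger = logging.getLogger(__name__)

PIPELINE_STAGES = ("simulate", "fc", "glm", "topology", "compare")

#: The study's standard contrasts: all patients vs all controls, the
#: two sex-stratified patient-control contrasts, and male vs female
#: within patients.
DEFAULT_CONTRASTS = (
    ("patient", "control"),
    ("patient:M", "control:M"),
    ("patient:F", "control:F"),
    ("patient:M", "patient:F"),
)


class IOError_(ValueError):
    """Raised for malformed input files or missing stage dependencies."""


def _header_comment(seed: int | None) -> str:
    return f"# fcnet {__version__} seed={seed}\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Cohort table


def write_cohort_table(
    records: list[SubjectRecord], path: str | Path, seed: int | None = None
) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group, "sex": r.sex,
          "age": r.age, "bmi": r.bmi, "mjoa": r.mjoa} for r in records]
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        frame.to_csv(fh, index=False)
    return path


def read_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Parse and validate a cohort CSV.

    Rejects missing columns, invalid enumerations, out-of-range mJOA
    (controls must score 18), and duplicated subject ids — each error
    cites the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    required = ["subject_id", "group", "sex", "age", "bmi", "mjoa"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise IOError_(f"{path}: missing column(s) {missing}")
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        rowno = int(idx) + 2  # 1-based, after the header line
        sid = str(row["subject_id"])
        if sid in seen:
            raise IOError_(f"{path}:row {rowno}: duplicated subject_id {sid!r}")
        seen.add(sid)
        try:
            records.append(SubjectRecord(
                subject_id=sid, group=str(row["group"]), sex=str(row["sex"]),
                age=float(row["age"]), bmi=float(row["bmi"]),
                mjoa=int(row["mjoa"]),
            ))
        except (DesignError, ValueError) as err:
            raise IOError_(f"{path}:row {rowno}: {err}") from err
    return records


# ---------------------------------------------------------------------------
# Matrices


def write_series(ts: ROITimeSeries, path: str | Path,
                 seed: int | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write("\t".join(ts.roi_labels) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.10g")
    return path


def read_series(
    path: str | Path,
    subject_id: str | None = None,
    sampling_interval: float = 2.0,
) -> ROITimeSeries:
    """Read a T x N series TSV: one header row of ROI labels."""
    path = Path(path)
    labels, data = _read_tsv_matrix(path)
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        data=data,
        roi_labels=labels,
        sampling_interval=sampling_interval,
    )


def write_connectivity(cm: ConnectivityMatrix, path: str | Path,
                       seed: int | None = None) -> Path:
    """Square TSV with ROI labels as header row and first column."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write("roi\t" + "\t".join(cm.roi_labels) + "\n")
        for label, row in zip(cm.roi_labels, cm.z):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_connectivity(path: str | Path,
                      subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a square labeled TSV; asymmetry beyond 1e-8 is an error."""
    path = Path(path)
    rows = [ln.rstrip("\n") for ln in path.read_text().splitlines()
            if ln and not ln.startswith("#")]
    header = rows[0].split("\t")
    if header[0] != "roi":
        raise IOError_(f"{path}: square matrix must start with a 'roi' column")
    labels = header[1:]
    n = len(labels)
    matrix = np.empty((n, n))
    if len(rows) - 1 != n:
        raise IOError_(f"{path}: expected {n} data rows, found {len(rows) - 1}")
    for i, line in enumerate(rows[1:]):
        parts = line.split("\t")
        if len(parts) != n + 1:
            raise IOError_(f"{path}: ragged row {i + 1} "
                           f"({len(parts) - 1} of {n} values)")
        if parts[0] != labels[i]:
            raise IOError_(f"{path}: row label {parts[0]!r} does not match "
                           f"header label {labels[i]!r}")
        try:
            matrix[i] = [float(v) for v in parts[1:]]
        except ValueError as err:
            raise IOError_(f"{path}: non-numeric cell in row {i + 1}: {err}")
    asym = np.abs(matrix - matrix.T)
    if asym.max() > 1e-8:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise IOError_(
            f"{path}: matrix asymmetric at ({labels[i]}, {labels[j]}): "
            f"|difference| = {asym[i, j]:.3g}"
        )
    matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, 0.0)
    return ConnectivityMatrix(subject_id=subject_id or path.stem,
                              z=matrix, roi_labels=labels)


def _read_tsv_matrix(path: Path) -> tuple[list[str], np.ndarray]:
    lines = [ln for ln in path.read_text().splitlines()
             if ln and not ln.startswith("#")]
    if not lines:
        raise IOError_(f"{path}: empty matrix file")
    labels = lines[0].split("\t")
    n = len(labels)
    data = np.empty((len(lines) - 1, n))
    for i, line in enumerate(lines[1:]):
        parts = line.split("\t")
        if len(parts) != n:
            raise IOError_(f"{path}: ragged row {i + 1} "
                           f"({len(parts)} of {n} values)")
        try:
            data[i] = [float(v) for v in parts]
        except ValueError as err:
            raise IOError_(f"{path}: non-numeric cell in row {i + 1}: {err}")
    if not np.all(np.isfinite(data)):
        raise IOError_(f"{path}: matrix contains non-finite values")
    return labels, data


def read_matrix(path: str | Path, kind: str = "series", **kwargs):
    """Dispatch by declared kind: 'series' (T x N) or 'square' (N x N)."""
    if kind == "series":
        return read_series(path, **kwargs)
    if kind == "square":
        return read_connectivity(path, **kwargs)
    raise IOError_(f"unknown matrix kind {kind!r}")


def write_table(frame: pd.DataFrame, path: str | Path,
                seed: int | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        frame.to_csv(fh, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable as YAML or JSON."""

    output_dir: str = "fcnet_out"
    cohort_table: str | None = None  # defaults to <output_dir>/cohort.csv
    series_dir: str | None = None  # defaults to <output_dir>/series
    contrasts: tuple = DEFAULT_CONTRASTS
    alpha_conn: float = DEFAULT_ALPHA_CONN
    alpha_fdr: float = DEFAULT_ALPHA_FDR
    fdr_scope: str = "seed"
    center_covariates: bool = True
    covariates: tuple[str, ...] = ("age", "bmi")
    taus: tuple[float, ...] = DEFAULT_TAUS
    reps: int = DEFAULT_NULL_REPS
    mode: str = "weighted"
    negatives: str = "drop"
    bandpass_low_hz: float = DEFAULT_BANDPASS_LOW_HZ
    bandpass_high_hz: float = DEFAULT_BANDPASS_HIGH_HZ
    pipeline_order: str = "filter_then_regress"
    sampling_interval: float = 2.0
    seed: int = 0
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tau in self.taus:
            if not 0 < tau <= 1:
                raise IOError_(f"tau {tau} outside (0, 1]")
        for alpha in (self.alpha_conn, self.alpha_fdr):
            if not 0 < alpha < 1:
                raise IOError_(f"alpha {alpha} outside (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise IOError_(f"unknown config key(s): {sorted(unknown)}")
        if "contrasts" in data:
            data["contrasts"] = tuple(tuple(c) for c in data["contrasts"])
        if "taus" in data:
            data["taus"] = tuple(float(t) for t in data["taus"])
        if "covariates" in data:
            data["covariates"] = tuple(data["covariates"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["contrasts"] = [list(c) for c in self.contrasts]
        out["taus"] = [float(t) for t in self.taus]
        out["covariates"] = list(self.covariates)
        return out

    def resolve_cohort_table(self) -> Path:
        return Path(self.cohort_table or Path(self.output_dir) / "cohort.csv")

    def resolve_series_dir(self) -> Path:
        return Path(self.series_dir or Path(self.output_dir) / "series")


def design_from_config(cfg: RunConfig) -> CohortDesign:
    """Build a CohortDesign from the config's ``design`` mapping.

    Unspecified fields fall back to the module defaults; ROI labels
    default to the synthetic parcellation of the requested size.
    """
    spec = dict(cfg.design)
    n_rois = int(spec.pop("n_rois", 132))
    if "roi_labels" in spec:
        labels = list(spec.pop("roi_labels"))
        partition = dict(spec.pop("module_partition"))
    else:
        labels, partition = default_parcellation(n_rois)
    n_per_cell = {
        tuple(k.split(":")): int(v)
        for k, v in spec.pop(
            "n_per_cell",
            {"patient:M": 10, "patient:F": 10,
             "control:M": 10, "control:F": 10},
        ).items()
    }
    edge_effects = [
        EdgeEffect(roi_i=e["roi_i"], roi_j=e["roi_j"],
                   delta_r=float(e["delta_r"]),
                   group=e.get("group"), sex=e.get("sex"))
        for e in spec.pop("edge_effects", [])
    ]
    topo_raw = spec.pop("topology_effects", {})
    topology_effects: dict[tuple[str, str], float] = {}
    for key, val in topo_raw.items():
        if ":" in key:
            topology_effects[tuple(key.split(":"))] = float(val)
        else:  # group-only selector expands to both sexes
            for cell in CELLS:
                if cell[0] == key:
                    topology_effects[cell] = float(val)
    return CohortDesign(
        roi_labels=labels,
        module_partition=partition,
        n_per_cell=n_per_cell,
        edge_effects=edge_effects,
        topology_effects=topology_effects,
        seed=int(spec.pop("seed", cfg.seed)),
        sampling_interval=float(spec.pop("sampling_interval",
                                         cfg.sampling_interval)),
        **spec,
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunManifest:
    """Config snapshot, seeds, and checksums of every written artifact."""

    version: str
    seed: int
    config: dict
    stages: dict[str, list[dict]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, stage: str, path: Path) -> None:
        self.stages.setdefault(stage, []).append(
            {"path": str(path), "sha256": _sha256(path)}
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path


def _parse_contrast(pair: tuple[str, str]) -> tuple[tuple[str, str], str | None]:
    """Selector pair -> (group contrast, sex restriction) for the GLM."""
    def split(sel: str) -> tuple[str, str | None]:
        if ":" in sel:
            g, s = sel.split(":", 1)
            return g, s
        return sel, None

    (ga, sa), (gb, sb) = split(pair[0]), split(pair[1])
    if ga == gb:
        if sa == sb:
            raise IOError_(f"contrast {pair} compares a cohort with itself")
        return (ga, gb), None  # within-group sex contrast
    if sa != sb:
        raise IOError_(
            f"contrast {pair} crosses both group and sex; restrict one"
        )
    return (ga, gb), sa


def _contrast_tag(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}".replace(":", "")


def run_pipeline(
    config: RunConfig, stages: tuple[str, ...] = PIPELINE_STAGES
) -> RunManifest:
    """Run the requested stages in canonical order and emit a manifest.

    Stage dependencies are checked up front: ``fc`` needs series and a
    cohort table, ``glm``/``topology`` need ``fc`` outputs, ``compare``
    needs ``topology`` outputs. Missing artifacts raise with the absent
    path named. Identical config + seed reproduce identical outputs
    (and therefore identical manifest checksums).
    """
    unknown = set(stages) - set(PIPELINE_STAGES)
    if unknown:
        raise IOError_(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in PIPELINE_STAGES if s in stages]
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=config.seed,
                           config=config.to_dict())

    cohort_path = config.resolve_cohort_table()
    series_dir = config.resolve_series_dir()
    fc_dir = outdir / "fc"
    topo_dir = outdir / "topology"

    if "simulate" in ordered:
        design = design_from_config(config)
        cohort = generate_cohort(design)
        series_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_table(cohort.records, cohort_path, seed=config.seed)
        manifest.add("simulate", cohort_path)
        for sid in sorted(cohort.series):
            p = write_series(cohort.series[sid], series_dir / f"{sid}.tsv",
                             seed=config.seed)
            manifest.add("simulate", p)
            logger.info("simulate: wrote %s", p)
        truth = pd.DataFrame(
            [{"roi_i": e.roi_i, "roi_j": e.roi_j, "delta_r": e.delta_r,
              "group": e.group or "*", "sex": e.sex or "*"}
             for e in cohort.truth.perturbed_edges]
        )
        p = write_table(truth, outdir / "truth_edges.tsv", seed=config.seed)
        manifest.add("simulate", p)

    if "fc" in ordered:
        if not cohort_path.exists():
            raise IOError_(f"fc stage needs cohort table {cohort_path}")
        records = read_cohort_table(cohort_path)
        fc_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            sp = series_dir / f"{rec.subject_id}.tsv"
            if not sp.exists():
                raise IOError_(f"fc stage: missing series file {sp}")
            ts = read_series(sp, subject_id=rec.subject_id,
                             sampling_interval=config.sampling_interval)
            cm = preprocess_and_connect(
                ts, low_hz=config.bandpass_low_hz,
                high_hz=config.bandpass_high_hz,
                order=config.pipeline_order,
            )
            p = write_connectivity(cm, fc_dir / f"{rec.subject_id}.tsv",
                                   seed=config.seed)
            manifest.add("fc", p)
            logger.info("fc: wrote %s", p)

    if "glm" in ordered or "topology" in ordered or "compare" in ordered:
        if not cohort_path.exists():
            raise IOError_(f"downstream stages need cohort table {cohort_path}")
        records = read_cohort_table(cohort_path)

    if "glm" in ordered or "topology" in ordered:
        if not fc_dir.exists():
            raise IOError_(f"stage needs fc outputs under {fc_dir}")
        matrices = []
        for rec in records:
            p = fc_dir / f"{rec.subject_id}.tsv"
            if not p.exists():
                raise IOError_(f"missing connectivity matrix {p}")
            matrices.append(read_connectivity(p, subject_id=rec.subject_id))

    if "glm" in ordered:
        glm_dir = outdir / "glm"
        glm_dir.mkdir(parents=True, exist_ok=True)
        for pair in config.contrasts:
            contrast, sex = _parse_contrast(tuple(pair))
            table = fit_contrast(
                records, matrices, contrast=contrast, sex=sex,
                covariates=config.covariates,
                alpha_conn=config.alpha_conn, alpha_fdr=config.alpha_fdr,
                fdr_scope=config.fdr_scope,
                center=config.center_covariates,
            )
            p = write_table(table.table, glm_dir / f"{_contrast_tag(pair)}.tsv",
                            seed=config.seed)
            manifest.add("glm", p)
            logger.info("glm: %s -> %d significant edges",
                        _contrast_tag(pair),
                        int(table.table["significant"].sum()))

    if "topology" in ordered:
        topo_dir.mkdir(parents=True, exist_ok=True)
        auc_rows = []
        rec_by_id = {r.subject_id: r for r in records}
        for cm in matrices:
            curve = topology_curve(
                cm, taus=config.taus, reps=config.reps,
                seed=np.random.SeedSequence(
                    [config.seed, _stable_id_hash(cm.subject_id)]
                ).generate_state(1)[0] % (2**31),
                mode=config.mode, negatives=config.negatives,
            )
            frame = pd.DataFrame({
                "tau": curve.taus, "C": curve.c_curve, "L": curve.l_curve,
                "gamma": curve.gamma_curve, "lambda": curve.lambda_curve,
                "sigma": curve.sigma_curve,
                "unreachable_pairs": curve.unreachable_curve,
            })
            p = write_table(frame, topo_dir / f"{cm.subject_id}_curve.tsv",
                            seed=config.seed)
            manifest.add("topology", p)
            rec = rec_by_id[cm.subject_id]
            auc_rows.append({
                "subject_id": cm.subject_id, "group": rec.group,
                "sex": rec.sex, "cohort": f"{rec.group}:{rec.sex}",
                "auc_c": curve.auc_c, "auc_l": curve.auc_l,
                "auc_sigma": curve.auc_sigma, "mode": curve.mode,
                "reps": curve.reps, "seed": curve.seed,
            })
            logger.info("topology: %s auc_c=%.4f auc_l=%.4f",
                        cm.subject_id, curve.auc_c, curve.auc_l)
        p = write_table(pd.DataFrame(auc_rows), topo_dir / "auc.tsv",
                        seed=config.seed)
        manifest.add("topology", p)

    if "compare" in ordered:
        auc_path = topo_dir / "auc.tsv"
        if not auc_path.exists():
            raise IOError_(f"compare stage needs AUC table {auc_path}")
        aucs = pd.read_csv(auc_path, sep="\t", comment="#")
        cmp_dir = outdir / "compare"
        cmp_dir.mkdir(parents=True, exist_ok=True)
        all_results = []
        for pair in config.contrasts:
            sel_a, sel_b = pair
            labeled = _label_cohorts(aucs, records, sel_a, sel_b)
            all_results.extend(compare_topology_auc(labeled, (sel_a, sel_b)))
            for variable in ("age", "bmi", "mjoa"):
                all_results.append(
                    compare_demographics(records, (sel_a, sel_b), variable)
                )
        p = write_table(results_table(all_results),
                        cmp_dir / "comparisons.tsv", seed=config.seed)
        manifest.add("compare", p)

    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    logger.info("manifest written to %s", manifest_path)
    return manifest


def _stable_id_hash(subject_id: str) -> int:
    import zlib

    return zlib.crc32(subject_id.encode())


def _label_cohorts(
    aucs: pd.DataFrame, records: list[SubjectRecord], sel_a: str, sel_b: str
) -> pd.DataFrame:
    """Relabel the AUC table's cohort column for one selector contrast."""
    ids_a = {r.subject_id for r in _select(records, sel_a)}
    ids_b = {r.subject_id for r in _select(records, sel_b)}
    out = aucs.copy()
    out["cohort"] = [
        sel_a if s in ids_a else (sel_b if s in ids_b else "")
        for s in out["subject_id"]
    ]
    return out[out["cohort"] != ""]
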