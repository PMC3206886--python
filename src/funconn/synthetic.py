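"""Synthetic resting-state cohort generator.

The generator realizes multi-subject region x time BOLD-like signals with
the statistical structure the downstream network analysis assumes:

* a modular (block) correlation structure — regions are partitioned into
  communities with high within- and low between-community correlation;
* a 2x2 sex-by-disease design in which disease reduces within-community
  coupling on a designated "affected" region set, with an extra reduction in
  the female-patient cell (the interaction);
* a per-patient disease-duration covariate that linearly modulates the same
  coupling, supporting age-controlled partial-correlation recovery;
* nuisance components (six rigid-body motion traces, a white-matter and a
  ventricle signal) linearly mixed into the regional signals with recorded
  weights, so preprocessing can be verified to remove them.

Time series are drawn from a multivariate normal with the subject's block
correlation matrix and passed through a common AR(1) filter, which adds
realistic temporal autocorrelation while leaving the contemporaneous
(Pearson) correlation structure intact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .config import AAL90_LABELS, CohortConfig, ConfigurationError
from .graph import BinaryGraph

__all__ = [
    "SubjectRecord",
    "RoiTimeSeries",
    "NuisanceSet",
    "Cohort",
    "generate_cohort",
    "generate_fixture_graph",
    "module_assignment",
]


@dataclass(frozen=True)
class SubjectRecord:
    """Demographic and clinical covariates of one subject.

    Clinical fields (disease duration, attack frequency/duration, pain
    intensity) are ``None`` for controls.
    """

    subject_id: str
    sex: str                      # "male" | "female"
    group: str                    # "patient" | "control"
    age: float
    disease_duration: float | None = None   # years
    attack_frequency: float | None = None   # attacks per 4 weeks
    attack_duration: float | None = None    # hours
    pain_intensity: float | None = None     # 0-10 scale

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.group not in ("patient", "control"):
            raise ValueError(f"invalid group {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.group == "control":
            for f in ("disease_duration", "attack_frequency", "attack_duration",
                      "pain_intensity"):
                if getattr(self, f) is not None:
                    raise ValueError(f"control subject must not carry {f}")
        elif self.pain_intensity is not None and not 0 <= self.pain_intensity <= 10:
            raise ValueError("pain_intensity must lie in [0, 10]")


@dataclass
class RoiTimeSeries:
    """One subject's region x time signal matrix with sampling interval."""

    region_labels: tuple[str, ...]
    data: np.ndarray              # (n_regions, n_timepoints)
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x time)")
        self.region_labels = tuple(self.region_labels)
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError("row count must equal label count")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceSet:
    """Nuisance regressors accompanying one subject's time series.

    ``mixing_weights`` is ground truth recorded by the simulator (regions x 8
    loadings onto [motion x6, wm, csf]); it is ``None`` for real data.
    """

    motion: np.ndarray            # (6, T): 3 translations mm, 3 rotations deg
    wm_signal: np.ndarray         # (T,)
    csf_signal: np.ndarray        # (T,)
    mixing_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=np.float64)
        self.wm_signal = np.asarray(self.wm_signal, dtype=np.float64).ravel()
        self.csf_signal = np.asarray(self.csf_signal, dtype=np.float64).ravel()
        if self.motion.ndim != 2 or self.motion.shape[0] != 6:
            raise ValueError("motion must be a 6 x T matrix")
        t = self.motion.shape[1]
        if self.wm_signal.shape[0] != t or self.csf_signal.shape[0] != t:
            raise ValueError("nuisance components must share one time length")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[1]

    def design(self) -> np.ndarray:
        """All eight regressors stacked as a (8, T) matrix."""
        return np.vstack([self.motion, self.wm_signal, self.csf_signal])


@dataclass
class Cohort:
    """A generated cohort: records plus per-subject signals and nuisance."""

    subjects: list[SubjectRecord]
    timeseries: dict[str, RoiTimeSeries]
    nuisance: dict[str, NuisanceSet]
    config: CohortConfig


# -- clinical covariate distributions (cell means +/- SD) --------------------

_CELL_MOMENTS = {
    # (sex, group): dict of field -> (mean, sd)
    ("female", "control"): {"age": (31.1, 9.3)},
    ("male", "control"): {"age": (33.3, 2.1)},
    ("female", "patient"): {
        "age": (32.3, 8.7), "disease_duration": (10.9, 7.4),
        "attack_duration": (12.9, 7.7), "attack_frequency": (4.0, 1.9),
        "pain_intensity": (5.4, 1.7),
    },
    ("male", "patient"): {
        "age": (33.0, 7.9), "disease_duration": (8.1, 2.3),
        "attack_duration": (14.5, 4.4), "attack_frequency": (4.4, 2.1),
        "pain_intensity": (5.2, 1.2),
    },
}

_FIELD_BOUNDS = {
    "age": (18.0, 70.0),
    "disease_duration": (0.5, 40.0),
    "attack_duration": (1.0, 72.0),
    "attack_frequency": (0.5, 28.0),
    "pain_intensity": (0.0, 10.0),
}


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random()
    return float(sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd))


def _expected_duration_mean(config: CohortConfig) -> float:
    """Population mean disease duration implied by the cell moments."""
    nf, nm = config.n_females_per_group, config.n_males_per_group
    mf = _CELL_MOMENTS[("female", "patient")]["disease_duration"][0]
    mm = _CELL_MOMENTS[("male", "patient")]["disease_duration"][0]
    return (nf * mf + nm * mm) / (nf + nm)


def module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous community labels (0..n_modules-1) for each region."""
    sizes = np.full(n_modules, n_regions // n_modules)
    sizes[: n_regions % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def _nearest_correlation(r: np.ndarray, eig_floor: float = 1e-4) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are floored at ``eig_floor`` and the diagonal renormalized
    to 1; for the mild perturbations the generator applies this leaves the
    matrix essentially unchanged whenever it is already positive definite.
    """
    w, v = np.linalg.eigh((r + r.T) / 2)
    if w.min() >= eig_floor:
        out = r.copy()
    else:
        out = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2


def _base_block_correlation(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    modules = module_assignment(config.n_regions, config.n_modules)
    same = modules[:, None] == modules[None, :]
    r = np.where(same, config.within_module_r, config.between_module_r)
    np.fill_diagonal(r, 1.0)
    return r, modules


def _subject_correlation(config: CohortConfig, modules: np.ndarray,
                         base: np.ndarray, record: SubjectRecord,
                         duration_center: float) -> np.ndarray:
    """Base block correlation plus this subject's coupling perturbation."""
    if record.group == "control":
        delta = 0.0
    else:
        delta = -config.disease_effect
        if record.sex == "female":
            delta -= config.sex_disease_interaction
        if record.disease_duration is not None:
            delta += config.duration_slope * (record.disease_duration - duration_center)
    if delta == 0.0:
        return base
    if config.affected_regions is None:
        affected = np.nonzero(modules == 0)[0]
    else:
        affected = np.asarray(config.affected_regions)
    mask = np.zeros(config.n_regions, dtype=bool)
    mask[affected] = True
    same_module = modules[:, None] == modules[None, :]
    pair_mask = np.outer(mask, mask) & same_module
    np.fill_diagonal(pair_mask, False)
    r = base.copy()
    r[pair_mask] = np.clip(r[pair_mask] + delta, -0.97, 0.97)
    return _nearest_correlation(r)


def _ar1_series(rng: np.random.Generator, chol: np.ndarray, n_timepoints: int,
                phi: float, burn: int = 50) -> np.ndarray:
    """Stationary AR(1) process with innovation correlation ``chol @ chol.T``.

    All regions share the AR coefficient, so the contemporaneous correlation
    equals the innovation correlation exactly in the stationary regime.
    """
    n = chol.shape[0]
    innov = chol @ rng.standard_normal((n, n_timepoints + burn))
    if phi == 0.0:
        return innov[:, burn:]
    x = np.empty_like(innov)
    scale = np.sqrt(1.0 - phi * phi)
    x[:, 0] = innov[:, 0]
    for t in range(1, innov.shape[1]):
        x[:, t] = phi * x[:, t - 1] + scale * innov[:, t]
    return x[:, burn:]


def _motion_traces(rng: np.random.Generator, n_timepoints: int,
                   step_sd: float = 0.01) -> np.ndarray:
    """Six slow random-walk rigid-body parameters (mm / degrees)."""
    steps = rng.normal(0.0, step_sd, size=(6, n_timepoints))
    steps[:, 0] = 0.0
    return np.cumsum(steps, axis=1)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _make_records(config: CohortConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    records: list[SubjectRecord] = []
    i = 0
    for group in ("patient", "control"):
        for sex, count in (("female", config.n_females_per_group),
                           ("male", config.n_males_per_group)):
            moments = _CELL_MOMENTS[(sex, group)]
            for _ in range(count):
                i += 1
                fields = {}
                for name, (mean, sd) in moments.items():
                    lo, hi = _FIELD_BOUNDS[name]
                    fields[name] = round(_truncnorm_draw(rng, mean, sd, lo, hi), 2)
                records.append(SubjectRecord(
                    subject_id=f"sub-{i:03d}", sex=sex, group=group, **fields,
                ))
    return records


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort from a :class:`CohortConfig`.

    Returns a :class:`Cohort` whose ``subjects`` list matches the configured
    cell counts, with each subject's region x time matrix realized from their
    perturbed block correlation and the recorded nuisance components mixed in.
    """
    config = config or CohortConfig()
    if config.n_regions == 90:
        labels = AAL90_LABELS
    else:
        labels = tuple(f"R{i:03d}" for i in range(config.n_regions))

    base, modules = _base_block_correlation(config)
    base = _nearest_correlation(base)
    duration_center = _expected_duration_mean(config)

    root = np.random.SeedSequence(config.seed)
    rec_rng = np.random.default_rng(root.spawn(1)[0])
    records = _make_records(config, rec_rng)

    subject_seeds = root.spawn(len(records))
    timeseries: dict[str, RoiTimeSeries] = {}
    nuisance: dict[str, NuisanceSet] = {}
    chol_cache: dict[bytes, np.ndarray] = {}

    for record, seed in zip(records, subject_seeds):
        rng = np.random.default_rng(seed)
        r = _subject_correlation(config, modules, base, record, duration_center)
        key = r.tobytes()
        if key not in chol_cache:
            chol_cache[key] = np.linalg.cholesky(r)
        signal = _ar1_series(rng, chol_cache[key], config.n_timepoints,
                             config.noise_ar1)
        signal = _standardize_rows(signal)

        motion = _motion_traces(rng, config.n_timepoints)
        wm = _ar1_series(rng, np.eye(1), config.n_timepoints, config.noise_ar1)[0]
        csf = _ar1_series(rng, np.eye(1), config.n_timepoints, config.noise_ar1)[0]
        regressors = _standardize_rows(np.vstack([motion, wm, csf]))
        weights = rng.normal(0.0, config.nuisance_amplitude / np.sqrt(8.0),
                             size=(config.n_regions, 8))
        data = signal + weights @ regressors

        timeseries[record.subject_id] = RoiTimeSeries(labels, data, config.tr_seconds)
        nuisance[record.subject_id] = NuisanceSet(motion, wm, csf, weights)

    return Cohort(records, timeseries, nuisance, config)


# -- deterministic / seeded fixture graphs -----------------------------------

_FIXTURE_KINDS = ("ring_lattice", "watts_strogatz", "erdos_renyi", "star",
                  "path", "cycle", "complete")


def generate_fixture_graph(kind: str, n_nodes: int, params: dict | None = None,
                           seed: int | None = None) -> BinaryGraph:
    """Canonical test-fixture graphs as :class:`BinaryGraph` objects.

    ``kind`` is one of ring_lattice, watts_strogatz (params: k, p),
    erdos_renyi (params: p), star, path, cycle, complete.  Random kinds
    require a seed and are fully reproducible.
    """
    import networkx as nx

    params = dict(params or {})
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if kind == "ring_lattice":
        g = nx.watts_strogatz_graph(n_nodes, params.pop("k"), 0.0)
    elif kind == "watts_strogatz":
        g = nx.connected_watts_strogatz_graph(
            n_nodes, params.pop("k"), params.pop("p"), seed=seed)
    elif kind == "erdos_renyi":
        g = nx.gnp_random_graph(n_nodes, params.pop("p"), seed=seed)
    elif kind == "star":
        g = nx.star_graph(n_nodes - 1)
    elif kind == "path":
        g = nx.path_graph(n_nodes)
    elif kind == "cycle":
        g = nx.cycle_graph(n_nodes)
    elif kind == "complete":
        g = nx.complete_graph(n_nodes)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of "
                         f"{_FIXTURE_KINDS}")
    if params:
        raise ValueError(f"unused params for kind {kind!r}: {sorted(params)}")
    return BinaryGraph.from_networkx(g)
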