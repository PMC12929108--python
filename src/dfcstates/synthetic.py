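"""Markov-switching multivariate-normal cohort simulator.

Generates multi-subject, multi-group region-of-interest (ROI) time series in
which the instantaneous correlation structure switches among a small number of
latent connectivity states according to a per-group first-order Markov chain.
Each time point is drawn from a zero-mean multivariate normal with the
covariance of the currently active state, so the latent process operates at
the time-point level and sliding windows near state boundaries mix states —
the regime a window-based clustering pipeline must tolerate.

The default configuration plants three states with strong / sparse /
intermediate mean connectivity and stationary occupancies of roughly
36.5 / 57.2 / 6.2 %, over a three-group cohort (healthy-control,
herpes-zoster and postherpetic-neuralgia analogues) whose group differences
are injected through the transition matrix (state occupancy and dwell shifts)
and through per-state nodal edge perturbations.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StructureError",
    "ConfigurationError",
    "LatentStateModel",
    "GroupSpec",
    "SubjectRecord",
    "SyntheticCohort",
    "make_state_covariances",
    "dwell_transition_matrix",
    "reversible_transition_matrix",
    "simulate_subject",
    "simulate_cohort",
    "default_latent_model",
    "default_group_specs",
    "default_cohort",
    "ground_truth_window_labels",
    "write_cohort",
]

#: maximum diagonal loading applied while repairing an indefinite matrix
MAX_DIAGONAL_LOADING = 0.5
#: loading increment per repair step
DIAGONAL_LOADING_STEP = 0.01
_PD_EPS = 1e-10
_STOCHASTIC_TOL = 1e-12


class StructureError(ValueError):
    """A requested covariance structure cannot be made positive definite."""


class ConfigurationError(ValueError):
    """A cohort/group configuration is inconsistent."""


# ---------------------------------------------------------------------------
# latent model
# ---------------------------------------------------------------------------

@dataclass
class LatentStateModel:
    """Latent connectivity-state model: per-state covariances + Markov chain.

    Parameters
    ----------
    state_covariances
        One symmetric positive-definite N x N matrix per state (unit
        diagonal by construction when built with
        :func:`make_state_covariances`).
    transition_matrix
        Row-stochastic ``n_states x n_states`` transition probabilities.
    initial_distribution
        Length ``n_states`` probability vector for the first time point.
    """

    state_covariances: list[np.ndarray]
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        self.state_covariances = [np.asarray(c, dtype=float) for c in self.state_covariances]
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        k = len(self.state_covariances)
        if k < 1:
            raise ConfigurationError("at least one latent state is required")
        n = self.state_covariances[0].shape[0]
        for i, c in enumerate(self.state_covariances):
            if c.shape != (n, n):
                raise ConfigurationError("state covariances must share one shape")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ConfigurationError(f"state {i + 1} covariance is not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ConfigurationError(f"state {i + 1} covariance is not positive definite")
        if self.transition_matrix.shape != (k, k):
            raise ConfigurationError("transition matrix shape must be (n_states, n_states)")
        if np.any(self.transition_matrix < 0):
            raise ConfigurationError("transition probabilities must be nonnegative")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=_STOCHASTIC_TOL):
            raise ConfigurationError("transition matrix rows must sum to 1")
        if self.initial_distribution.shape != (k,):
            raise ConfigurationError("initial distribution length must equal n_states")
        if np.any(self.initial_distribution < 0) or not np.isclose(
            self.initial_distribution.sum(), 1.0, atol=_STOCHASTIC_TOL
        ):
            raise ConfigurationError("initial distribution must be a probability vector")

    @property
    def n_states(self) -> int:
        return len(self.state_covariances)

    @property
    def n_rois(self) -> int:
        return self.state_covariances[0].shape[0]

    def with_overrides(
        self,
        transition_matrix: Optional[np.ndarray] = None,
        initial_distribution: Optional[np.ndarray] = None,
        nodal_perturbation: Optional[dict[int, Sequence[tuple[int, float]]]] = None,
    ) -> "LatentStateModel":
        """Return a copy with group-level overrides applied.

        ``nodal_perturbation`` maps a 0-based state index to ``(node, delta)``
        pairs; ``delta`` is added to every off-diagonal entry in the node's
        row/column of that state's covariance, then the matrix is re-repaired
        to positive definiteness.
        """
        covs = [c.copy() for c in self.state_covariances]
        if nodal_perturbation:
            for s, edits in nodal_perturbation.items():
                c = covs[s]
                for node, delta in edits:
                    mask = np.ones(c.shape[0], dtype=bool)
                    mask[node] = False
                    c[node, mask] = np.clip(c[node, mask] + delta, -0.95, 0.95)
                    c[mask, node] = c[node, mask]
                covs[s], load = _repair_spd(c)
                if load > 0:
                    logger.info("state %d perturbation repaired with loading %.2f", s + 1, load)
        return LatentStateModel(
            state_covariances=covs,
            transition_matrix=(
                self.transition_matrix if transition_matrix is None else transition_matrix
            ),
            initial_distribution=(
                self.initial_distribution
                if initial_distribution is None
                else initial_distribution
            ),
        )


def _repair_spd(c: np.ndarray) -> tuple[np.ndarray, float]:
    """Repair an indefinite correlation-scale matrix by diagonal loading.

    Adds ``load`` to the diagonal in steps of 0.01 and rescales back to unit
    diagonal (equivalently shrinks off-diagonals by ``1/(1+load)``) until the
    smallest eigenvalue is strictly positive.
    """
    load = 0.0
    while True:
        m = (c + load * np.eye(c.shape[0])) / (1.0 + load)
        if np.linalg.eigvalsh(m).min() > _PD_EPS:
            return m, load
        if load >= MAX_DIAGONAL_LOADING:
            raise StructureError(
                "covariance not positive definite after maximum diagonal loading"
            )
        load = round(load + DIAGONAL_LOADING_STEP, 10)


def make_state_covariances(
    n_rois: int,
    block_structure: Sequence[Sequence[tuple[Sequence[int], float]]],
    noise_floor: float = 0.0,
    seed: Optional[int] = None,
) -> list[np.ndarray]:
    """Build one SPD correlation-scale matrix per state from block specs.

    ``block_structure`` holds, per state, a list of ``(node_indices, level)``
    blocks: every off-diagonal pair within a block is set to ``level``.
    Pairs not covered by any block get ``noise_floor``. Indefinite requests
    are repaired by diagonal loading (see :func:`_repair_spd`).

    The ``seed`` argument is accepted for interface symmetry with the other
    simulators; the construction itself is deterministic.
    """
    del seed
    if n_rois < 4:
        raise ConfigurationError("n_rois must be at least 4")
    if not -1.0 < noise_floor < 1.0:
        raise ConfigurationError("noise_floor must lie in (-1, 1)")
    covs = []
    for state_blocks in block_structure:
        c = np.full((n_rois, n_rois), float(noise_floor))
        np.fill_diagonal(c, 1.0)
        for nodes, level in state_blocks:
            if not -1.0 < level < 1.0:
                raise ConfigurationError("block correlation levels must lie in (-1, 1)")
            idx = np.asarray(nodes, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n_rois):
                raise ConfigurationError("block node index out of range")
            sub = np.ix_(idx, idx)
            c[sub] = level
            c[idx, idx] = 1.0
        repaired, load = _repair_spd(c)
        if load > 0:
            logger.info("covariance repaired with diagonal loading %.2f", load)
        covs.append(repaired)
    return covs


def dwell_transition_matrix(
    stationary: Sequence[float], dwell_times: Sequence[float]
) -> np.ndarray:
    """Reversible chain with exact stationary ``pi`` and mean dwell times.

    ``P[i, i] = 1 - 1/dwell_i`` so the mean sojourn in state i is
    ``dwell_i`` time points; the off-diagonal entries solve detailed balance
    for the requested stationary distribution (three states: pairwise flows
    ``x_ij = (F_i + F_j - F_k)/2`` with ``F_i = pi_i/dwell_i``). Raises when
    no nonnegative flow solution exists for the requested combination.
    """
    pi = np.asarray(stationary, dtype=float)
    d = np.asarray(dwell_times, dtype=float)
    if pi.size != d.size:
        raise ConfigurationError("stationary and dwell_times must have equal length")
    if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0, atol=1e-9):
        raise ConfigurationError("stationary distribution must be positive and sum to 1")
    if np.any(d <= 1):
        raise ConfigurationError("dwell times must exceed 1 time point")
    pi = pi / pi.sum()
    k = pi.size
    f = pi / d  # outflow mass per state
    p = np.diag(1.0 - 1.0 / d)
    if k == 2:
        flows = {(0, 1): f[0]}
        if not np.isclose(f[0], f[1], atol=1e-12):
            raise ConfigurationError("two-state chain requires pi_0/d_0 == pi_1/d_1")
    elif k == 3:
        flows = {
            (0, 1): (f[0] + f[1] - f[2]) / 2.0,
            (0, 2): (f[0] + f[2] - f[1]) / 2.0,
            (1, 2): (f[1] + f[2] - f[0]) / 2.0,
        }
    else:
        raise ConfigurationError("dwell_transition_matrix supports 2 or 3 states")
    if any(x < 0 for x in flows.values()):
        raise ConfigurationError(
            "requested stationary/dwell combination admits no reversible chain"
        )
    for (i, j), x in flows.items():
        p[i, j] = x / pi[i]
        p[j, i] = x / pi[j]
    rows = p.sum(axis=1)
    if np.any(p < -1e-12) or not np.allclose(rows, 1.0, atol=1e-9):
        raise ConfigurationError("dwell construction produced an invalid chain")
    # absorb rounding so rows sum to 1 within 1e-12
    np.fill_diagonal(p, np.diag(p) + (1.0 - rows))
    return p


def reversible_transition_matrix(stationary: Sequence[float], jump_rate: float) -> np.ndarray:
    """Row-stochastic chain with the given stationary distribution.

    Off-diagonal ``P[i, j] = jump_rate * pi[j]``; the construction is
    reversible, so ``pi`` is exactly stationary. Smaller ``jump_rate`` means
    stickier states (mean dwell in state i is ``1 / (jump_rate * (1 - pi_i))``
    time points).
    """
    pi = np.asarray(stationary, dtype=float)
    if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0, atol=1e-9):
        raise ConfigurationError("stationary distribution must be positive and sum to 1")
    pi = pi / pi.sum()
    p = jump_rate * np.tile(pi, (pi.size, 1))
    np.fill_diagonal(p, 1.0 - jump_rate * (1.0 - pi))
    if np.any(np.diag(p) < 0):
        raise ConfigurationError("jump_rate too large for the requested stationary distribution")
    return p


# ---------------------------------------------------------------------------
# groups and cohort
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One cohort group: size, chain overrides, covariate distributions."""

    group_name: str
    n_subjects: int
    transition_matrix: Optional[np.ndarray] = None
    initial_distribution: Optional[np.ndarray] = None
    #: 0-based state index -> list of (node, delta) edge-weight edits
    nodal_perturbation: Optional[dict[int, list[tuple[int, float]]]] = None
    age_mean: float = 58.0
    age_sd: float = 8.0
    male_fraction: float = 0.5
    nrs_mean: Optional[float] = None
    nrs_sd: float = 0.0
    duration_mean: Optional[float] = None
    duration_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("group sizes must be nonnegative")
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=_STOCHASTIC_TOL):
                raise ConfigurationError(
                    f"group {self.group_name!r}: transition override must be row-stochastic"
                )
            self.transition_matrix = t


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    gender: int  # 1 = male, 0 = female
    series: np.ndarray  # T x N
    states: np.ndarray  # length T, values 1..n_states
    nrs: float = float("nan")
    duration: float = float("nan")


@dataclass
class SyntheticCohort:
    """Simulated cohort with per-subject ground-truth state sequences."""

    subjects: list[SubjectRecord]
    model: LatentStateModel
    seed: int
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i + 1:03d}" for i in range(self.model.n_rois)]
        k = self.model.n_states
        for s in self.subjects:
            if not np.all(np.isfinite(s.series)):
                raise ConfigurationError(f"subject {s.subject_id}: non-finite series values")
            if s.states.min() < 1 or s.states.max() > k:
                raise ConfigurationError(f"subject {s.subject_id}: state labels outside 1..K")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "gender": [s.gender for s in self.subjects],
                "nrs": [s.nrs for s in self.subjects],
                "duration": [s.duration for s in self.subjects],
            }
        )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    model: LatentStateModel,
    n_timepoints: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one subject: (T x N series, length-T 1-based state sequence).

    The state path is sampled from the Markov chain; each time point is drawn
    from a zero-mean multivariate normal with the active state's covariance.
    Deterministic given the seed.
    """
    if n_timepoints < 1:
        raise ConfigurationError("n_timepoints must be positive")
    rng = np.random.default_rng(seed)
    k, n = model.n_states, model.n_rois
    states = np.empty(n_timepoints, dtype=np.int64)
    # cumulative-probability inversion keeps the draw count fixed per step
    init_cdf = np.cumsum(model.initial_distribution)
    trans_cdf = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(n_timepoints)
    s = int(np.searchsorted(init_cdf, u[0], side="right"))
    s = min(s, k - 1)
    states[0] = s
    for t in range(1, n_timepoints):
        s = int(np.searchsorted(trans_cdf[s], u[t], side="right"))
        s = min(s, k - 1)
        states[t] = s
    chols = [np.linalg.cholesky(c) for c in model.state_covariances]
    z = rng.standard_normal((n_timepoints, n))
    series = np.empty_like(z)
    for j in range(k):
        mask = states == j
        if mask.any():
            series[mask] = z[mask] @ chols[j].T
    return series, states + 1


def simulate_cohort(
    model: LatentStateModel,
    groups: Sequence[GroupSpec],
    n_timepoints: int = 230,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a multi-group cohort with deterministic per-subject seeding.

    Per-subject random streams are spawned from the master seed, so the
    cohort is reproducible as a whole and subject-by-subject.
    """
    names = [g.group_name for g in groups]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate group names")
    if sum(g.n_subjects for g in groups) < 1:
        raise ConfigurationError("cohort must contain at least one subject")
    master = np.random.SeedSequence(seed)
    total = sum(g.n_subjects for g in groups)
    children = master.spawn(total)
    subjects: list[SubjectRecord] = []
    child_iter = iter(children)
    for g in groups:
        gmodel = model.with_overrides(
            transition_matrix=g.transition_matrix,
            initial_distribution=g.initial_distribution,
            nodal_perturbation=g.nodal_perturbation,
        )
        for i in range(g.n_subjects):
            child = next(child_iter)
            rng = np.random.default_rng(child)
            age = float(np.clip(rng.normal(g.age_mean, g.age_sd), 30.0, 80.0))
            gender = int(rng.random() < g.male_fraction)
            nrs = (
                float(max(0.0, rng.normal(g.nrs_mean, g.nrs_sd)))
                if g.nrs_mean is not None
                else float("nan")
            )
            duration = (
                float(max(0.0, rng.normal(g.duration_mean, g.duration_sd)))
                if g.duration_mean is not None
                else float("nan")
            )
            series, states = simulate_subject(gmodel, n_timepoints, rng)
            subjects.append(
                SubjectRecord(
                    subject_id=f"{g.group_name}{i + 1:02d}",
                    group=g.group_name,
                    age=age,
                    gender=gender,
                    nrs=nrs,
                    duration=duration,
                    series=series,
                    states=states,
                )
            )
    return SyntheticCohort(subjects=subjects, model=model, seed=seed)


# ---------------------------------------------------------------------------
# defaults: three states, three groups
# ---------------------------------------------------------------------------

#: stationary state shares of the base (healthy-control analogue) chain
BASE_STATIONARY = (0.3652, 0.5724, 0.0624)
#: mean dwell times (time points) of the base chain; long relative to the
#: 30-TR analysis window so most windows sample a single state, with the
#: rare intermediate state visited in short frequent bouts so its pooled
#: window count is stable across cohorts
BASE_DWELL = (150.0, 220.0, 35.0)
#: neuralgia-analogue chain: occupancy shifted out of the strong state into
#: the intermediate state, which also becomes stickier (longer dwell)
PHN_STATIONARY = (0.25, 0.55, 0.20)
PHN_DWELL = (130.0, 200.0, 65.0)


def default_latent_model(n_rois: int = 30) -> LatentStateModel:
    """Three planted states: strong, sparse and intermediate connectivity.

    State 1 carries three strong within-block couplings (thirds of the ROIs
    at 0.65; mean |off-diagonal| ~0.20), state 2 two weak half-size blocks
    (mean ~0.05), and state 3 moderate blocks (0.55) offset by half a block
    from state 1's partition (mean ~0.16) — a strong > intermediate >
    sparse tiering of mean absolute connectivity. Each state spreads its
    connectivity over several independent block factors, so windowed
    correlation estimates fluctuate incoherently across edges instead of
    along a single global-strength axis, and the offset block pattern keeps
    the intermediate state off the strong-sparse mixing line traced by
    windows that straddle a state boundary.
    """
    half = n_rois // 2
    third = n_rois // 3
    shift = third // 2
    strong = [
        (np.arange(0, third), 0.65),
        (np.arange(third, 2 * third), 0.65),
        (np.arange(2 * third, n_rois), 0.65),
    ]
    sparse = [(np.arange(0, half), 0.10), (np.arange(half, n_rois), 0.10)]
    intermediate = [
        (np.arange(shift, shift + third), 0.55),
        (np.arange(shift + third, shift + 2 * third), 0.55),
        (np.concatenate([np.arange(shift + 2 * third, n_rois), np.arange(0, shift)]), 0.55),
    ]
    covs = make_state_covariances(n_rois, [strong, sparse, intermediate])
    pi = np.asarray(BASE_STATIONARY)
    return LatentStateModel(
        state_covariances=covs,
        transition_matrix=dwell_transition_matrix(pi, BASE_DWELL),
        initial_distribution=pi,
    )


def default_group_specs(
    n_per_group: tuple[int, int, int] = (4, 4, 4), n_rois: int = 30
) -> list[GroupSpec]:
    """Three-group design: HC / HZ / PHN analogues.

    Age and gender distributions follow the cohort the generator emulates
    (HC 58.2 +/- 6.5 y, 14/27 male; HZ 60.4 +/- 10.2 y, 18/37 male;
    PHN 63.8 +/- 12.3 y, 10/18 male), ages clipped to the 30-80 y inclusion
    range. The PHN analogue gets a shifted, stickier chain (more occupancy
    and dwell in the intermediate state, less in the strong state) plus
    nodal edge perturbations in the strong state; the HZ analogue shares the
    base dynamics.
    """
    phn_pi = np.asarray(PHN_STATIONARY)
    return [
        GroupSpec(
            group_name="HC",
            n_subjects=n_per_group[0],
            age_mean=58.22,
            age_sd=6.49,
            male_fraction=14 / 27,
        ),
        GroupSpec(
            group_name="HZ",
            n_subjects=n_per_group[1],
            age_mean=60.38,
            age_sd=10.22,
            male_fraction=18 / 37,
            nrs_mean=5.95,
            nrs_sd=1.97,
            duration_mean=7.05,
            duration_sd=3.07,
        ),
        GroupSpec(
            group_name="PHN",
            n_subjects=n_per_group[2],
            transition_matrix=dwell_transition_matrix(phn_pi, PHN_DWELL),
            initial_distribution=phn_pi,
            nodal_perturbation={0: [(n_rois // 6, 0.12), (n_rois - 2, -0.18)]},
            age_mean=63.83,
            age_sd=12.25,
            male_fraction=10 / 18,
            nrs_mean=7.17,
            nrs_sd=1.79,
            duration_mean=2.1,
            duration_sd=2.76,
        ),
    ]


def default_cohort(
    seed: int,
    n_per_group: tuple[int, int, int] = (4, 4, 4),
    n_timepoints: int = 230,
    n_rois: int = 30,
) -> SyntheticCohort:
    """Default desk-scale cohort: 12 subjects x 230 time points x 30 ROIs."""
    return simulate_cohort(
        default_latent_model(n_rois),
        default_group_specs(n_per_group, n_rois),
        n_timepoints,
        seed,
    )


def ground_truth_window_labels(states: np.ndarray, width: int, step: int = 1) -> np.ndarray:
    """Majority ground-truth state per sliding window (ties -> lowest state)."""
    t = states.shape[0]
    n_win = (t - width) // step + 1
    out = np.empty(n_win, dtype=np.int64)
    for i in range(n_win):
        seg = states[i * step : i * step + width]
        counts = np.bincount(seg)
        out[i] = int(np.argmax(counts))
    return out


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write the cohort as delimited text + a JSON run descriptor.

    Layout: ``timeseries/<subject>.tsv`` (rows = time points, columns = ROI
    labels), ``manifest.tsv``, ``state_sequences.tsv`` (subject_id,
    timepoint, state) and ``cohort.json``. Regeneration with the same seed is
    byte-identical.
    """
    outdir = Path(outdir)
    tsdir = outdir / "timeseries"
    tsdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for s in cohort.subjects:
        p = tsdir / f"{s.subject_id}.tsv"
        pd.DataFrame(s.series, columns=cohort.roi_labels).to_csv(
            p, sep="\t", index=False, float_format="%.8g"
        )
        paths[s.subject_id] = str(p.relative_to(outdir))
    manifest = cohort.manifest_frame()
    manifest["path"] = [paths[sid] for sid in manifest["subject_id"]]
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False, float_format="%.8g")
    seq = pd.DataFrame(
        {
            "subject_id": np.repeat(
                [s.subject_id for s in cohort.subjects],
                [s.states.size for s in cohort.subjects],
            ),
            "timepoint": np.concatenate([np.arange(s.states.size) for s in cohort.subjects]),
            "state": np.concatenate([s.states for s in cohort.subjects]),
        }
    )
    seq.to_csv(outdir / "state_sequences.tsv", sep="\t", index=False)
    descriptor = {
        "seed": cohort.seed,
        "n_states": cohort.model.n_states,
        "n_rois": cohort.model.n_rois,
        "n_subjects": cohort.n_subjects,
        "groups": sorted({s.group for s in cohort.subjects}),
        "manifest": "manifest.tsv",
        "state_sequences": "state_sequences.tsv",
        "timeseries": paths,
    }
    (outdir / "cohort.json").write_text(json.dumps(descriptor, indent=2, sort_keys=True))
    return descriptor
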