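"""Synthetic multi-subject resting-state cohort with planted edge effects.

The generator emulates the statistical structure of a dementia-spectrum
resting-state study: three ordinal diagnostic groups (cognitively intact,
amnestic MCI, mild AD; default sizes 47/31/30), two runs of 1220 volumes at
TR = 0.737 s parcellated into 17 networks, rigid-body motion traces with a
sub-threshold noise floor plus Poisson-count spikes, a cognitive index on
the standard-score scale (M = 100, SD = 15, lower with increasing
severity), and nuisance covariates (age, sex, total brain volume,
education) with group offsets.

Signal model: volumes are i.i.d. zero-mean multivariate Gaussian draws
whose population correlation matrix is tanh of the subject's Fisher-z
connectivity targets, projected to the nearest positive-definite
correlation matrix.  Because the downstream pipeline only uses Pearson
correlation, i.i.d. sampling keeps the estimand exact and the sampling
variance analytic; temporal autocorrelation is deliberately not modeled.

Planted effects: for each (edge, rho) pair in ``effect_edges`` the
subject-level Fisher-z target depends linearly on the cognitive score so
that the population partial correlation between measured edge z and score,
given the analysis covariates (mean head motion, age, sex, brain volume),
equals rho.  The slope is solved from the realized cohort: with s~ the
score residualized on the covariates, b = rho * sigma_tot /
(sigma_s~ * sqrt(1 - rho^2)) where sigma_tot^2 combines the between-subject
edge noise and the analytic measurement variance 1/(n_runs*(n_volumes-3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import NETWORK_LABELS_17, edge_labels
from .motion import MotionTrace, framewise_displacement

DEFAULT_EFFECT_EDGES = (
    ("lateral_frontoparietal_CEN__dorsal_DMN", -0.38),
)


@dataclass
class ParcellatedRun:
    """One subject-run: volumes x networks BOLD with its motion trace."""

    subject_id: str
    run_id: str
    data: np.ndarray
    motion: MotionTrace
    tr_seconds: float
    labels: tuple


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: group sizes 47/31/30, 17 networks,
    2 runs x 1220 volumes at TR 0.737 s, scores on the standard-score scale
    with group means 100/85/70 and SD 15, age ~ N(74.1, 5.7^2) with the AD
    group older, and one planted negative edge-score effect.
    """

    group_sizes: tuple = (47, 31, 30)
    group_names: tuple = ("intact", "MCI", "AD")
    n_networks: int = 17
    n_volumes: int = 1220
    n_runs: int = 2
    tr_seconds: float = 0.737
    score_name: str = "score"
    score_means: tuple = (100.0, 85.0, 70.0)
    score_sd: float = 15.0
    effect_edges: tuple = DEFAULT_EFFECT_EDGES
    group_effect_edges: tuple = ()  # (edge_label, group_index, z_shift)
    spike_rate: float = 5.0
    spike_amplitude_mm: float = 2.0
    motion_floor_mm: float = 0.06
    motion_floor_sd_log: float = 0.3
    baseline_z_mean: float = 0.25
    baseline_z_sd: float = 0.08
    subject_z_sd: float = 0.08
    age_mean: float = 74.1
    age_sd: float = 5.7
    age_group_shift: tuple = (0.0, 0.0, 3.0)
    sex_p_female: float = 0.583
    tbv_mean: float = 1.10e6
    tbv_sd: float = 0.10e6
    tbv_group_shift: tuple = (0.0, -40e3, -60e3)
    education_mean: float = 16.1
    education_sd: float = 2.5
    education_group_shift: tuple = (0.0, -1.0, 0.0)
    age_z_slope: float = -0.002  # per-year drift applied to every edge
    tbv_z_slope: float = 2.0e-8  # per-mm^3 drift applied to every edge
    network_labels: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        if any(g < 0 for g in self.group_sizes):
            raise ValueError("group sizes must be non-negative")
        if sum(self.group_sizes) == 0:
            raise ValueError("cohort is empty")
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        if self.n_volumes < 4 or self.n_runs < 1:
            raise ValueError("need n_volumes >= 4 and n_runs >= 1")
        if self.spike_amplitude_mm <= 0:
            raise ValueError("spike_amplitude_mm must be positive")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be non-negative")
        if not self.network_labels:
            if self.n_networks == 17:
                self.network_labels = NETWORK_LABELS_17
            else:
                self.network_labels = tuple(
                    f"net{i + 1:02d}" for i in range(self.n_networks)
                )
        self.network_labels = tuple(self.network_labels)
        if len(self.network_labels) != self.n_networks:
            raise ValueError("network_labels length must equal n_networks")
        labels = set(edge_labels(self.network_labels))
        self.effect_edges = tuple((str(e), float(r)) for e, r in self.effect_edges)
        for edge, rho in self.effect_edges:
            if edge not in labels:
                raise ValueError(f"unknown effect edge {edge!r}")
            if not abs(rho) < 1:
                raise ValueError("planted partial correlations need |rho| < 1")
        self.group_effect_edges = tuple(
            (str(e), int(g), float(d)) for e, g, d in self.group_effect_edges
        )
        for edge, g, _ in self.group_effect_edges:
            if edge not in labels:
                raise ValueError(f"unknown group-effect edge {edge!r}")
            if not 0 <= g < len(self.group_sizes):
                raise ValueError(f"group index {g} out of range")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes)

    @property
    def edge_label_list(self) -> tuple:
        return edge_labels(self.network_labels)


def nearest_pd_correlation(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest positive-definite correlation matrix by eigenvalue clipping.

    Eigenvalues are clipped at ``eps`` and the result renormalized to a unit
    diagonal; deterministic and idempotent for already-PD inputs.
    """
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() >= eps:
        return R
    w = np.clip(w, eps, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    out = (R2 + R2.T) / 2.0
    if np.linalg.eigvalsh(out).min() <= 0:
        raise ValueError("positive-definite projection failed")
    return out


def make_phenotypes(spec: CohortSpec, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the phenotype table: group, score, and covariates per subject.

    Scores come from the per-group normal distributions; covariates use the
    configured means, SDs and group offsets.  Sex is coded 1 = female.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    sid = 0
    for g, size in enumerate(spec.group_sizes):
        for _ in range(size):
            sid += 1
            rows.append(
                {
                    "subject_id": f"sub-{sid:03d}",
                    "group": g,
                    "group_name": spec.group_names[g]
                    if g < len(spec.group_names) else str(g),
                    spec.score_name: rng.normal(spec.score_means[g], spec.score_sd),
                    "age": rng.normal(
                        spec.age_mean + spec.age_group_shift[g], spec.age_sd
                    ),
                    "sex": float(rng.random() < spec.sex_p_female),
                    "tbv": rng.normal(
                        spec.tbv_mean + spec.tbv_group_shift[g], spec.tbv_sd
                    ),
                    "education": rng.normal(
                        spec.education_mean + spec.education_group_shift[g],
                        spec.education_sd,
                    ),
                }
            )
    return pd.DataFrame(rows)


def _simulate_motion(spec: CohortSpec, rng: np.random.Generator,
                     subject_id: str, run_id: str) -> MotionTrace:
    """Random-walk motion trace with Poisson-count delta spikes.

    The noise floor is calibrated so per-transition RMS displacement sits
    far below the 0.5 mm censoring threshold; each spike adds
    ``spike_amplitude_mm`` to one translation channel of a single interior
    volume, tripping the two adjacent transitions.
    """
    n = spec.n_volumes
    sigma = spec.motion_floor_mm * np.exp(
        rng.normal(0.0, spec.motion_floor_sd_log)
    )
    steps = rng.normal(0.0, sigma, size=(n - 1, 6))
    steps[:, 3:] /= 50.0  # rotations stored in rad; arc at 50 mm ~ sigma
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    n_spikes = rng.poisson(spec.spike_rate)
    n_spikes = min(n_spikes, max(n - 2, 0))
    if n_spikes > 0 and n > 2:
        pos = rng.choice(np.arange(1, n - 1), size=n_spikes, replace=False)
        chan = rng.integers(0, 3, size=n_spikes)
        params[pos, chan] += spec.spike_amplitude_mm
    return MotionTrace(subject_id=subject_id, run_id=run_id, params=params)


def _population_score_residual(spec: CohortSpec, pheno: pd.DataFrame):
    """Score residual under the *population* linear projection on covariates.

    Among the analysis covariates only age and total brain volume are
    correlated with the score (through the shared group structure); sex and
    mean head motion are generated independently of group, so their
    population projection coefficients are zero.  Using the analytic mixture
    moments -- rather than a per-cohort least-squares fit -- keeps the
    planted effect's sampling variability honest: each simulated cohort's
    sample partial correlation then fluctuates around the planted value with
    the variance the Fisher-z interval assumes.

    Returns ``(s_tilde per subject, population residual SD)``.
    """
    pi = np.asarray(spec.group_sizes, dtype=float)
    pi = pi / pi.sum()
    m_s = np.asarray(spec.score_means[: len(pi)], dtype=float)
    m_a = spec.age_mean + np.asarray(spec.age_group_shift[: len(pi)], dtype=float)
    m_t = spec.tbv_mean + np.asarray(spec.tbv_group_shift[: len(pi)], dtype=float)

    def wmean(x):
        return float(np.dot(pi, x))

    def wcov(x, y):
        return float(np.dot(pi, x * y) - wmean(x) * wmean(y))

    var_s = spec.score_sd**2 + wcov(m_s, m_s)
    C = np.array(
        [
            [spec.age_sd**2 + wcov(m_a, m_a), wcov(m_a, m_t)],
            [wcov(m_a, m_t), spec.tbv_sd**2 + wcov(m_t, m_t)],
        ]
    )
    cov_sc = np.array([wcov(m_s, m_a), wcov(m_s, m_t)])
    gamma = np.linalg.solve(C, cov_sc)
    var_res = var_s - float(cov_sc @ gamma)
    if var_res <= 0:
        raise ValueError("score has no residual variance; cannot plant effects")
    s = pheno[spec.score_name].to_numpy()
    c = pheno[["age", "tbv"]].to_numpy() - np.array([wmean(m_a), wmean(m_t)])
    s_tilde = s - wmean(m_s) - c @ gamma
    return s_tilde, float(np.sqrt(var_res))


def _solve_effect_slopes(spec: CohortSpec, pheno: pd.DataFrame) -> dict:
    """Slope of Fisher-z target on residualized score per effect edge.

    Chosen so the population partial correlation of measured edge z with the
    score, given the analysis covariates, equals the planted value: b = rho *
    sigma_tot / (sigma_res * sqrt(1 - rho^2)), with sigma_tot^2 the
    between-subject edge noise plus the analytic i.i.d.-sampling measurement
    variance of the run-averaged Fisher z.
    """
    if not spec.effect_edges:
        return {}
    s_tilde, sigma_s = _population_score_residual(spec, pheno)
    meas_var = 1.0 / (spec.n_runs * max(spec.n_volumes - 3, 1))
    sigma_tot = np.sqrt(spec.subject_z_sd**2 + meas_var)
    return {
        edge: (rho * sigma_tot / (sigma_s * np.sqrt(1 - rho**2)), s_tilde)
        for edge, rho in spec.effect_edges
    }


def simulate_cohort(spec: CohortSpec):
    """Generate the full synthetic cohort.

    Returns ``(runs, phenotypes, truth)`` where ``runs`` maps subject id to
    its list of :class:`ParcellatedRun`, ``phenotypes`` is the analysis
    table (including the realized mean-motion covariate), and ``truth``
    records each subject's Fisher-z targets for the effect edges plus the
    planted values.  Bit-identical across reruns with the same spec.
    """
    rng = np.random.default_rng(spec.seed)
    pheno = make_phenotypes(spec, rng=rng)
    n_sub = len(pheno)
    labels = spec.network_labels
    elabels = spec.edge_label_list
    n_edges = len(elabels)
    edge_idx = {lab: j for j, lab in enumerate(elabels)}

    traces = {}
    mean_motion = np.empty(n_sub)
    for i, sid in enumerate(pheno["subject_id"]):
        subj_traces = [
            _simulate_motion(spec, rng, sid, f"run-{k + 1}")
            for k in range(spec.n_runs)
        ]
        traces[sid] = subj_traces
        mean_motion[i] = float(
            np.mean([framewise_displacement(t).mean() for t in subj_traces])
        )
    pheno = pheno.assign(mean_motion=mean_motion)

    baseline_z = rng.normal(spec.baseline_z_mean, spec.baseline_z_sd, size=n_edges)
    slopes = _solve_effect_slopes(spec, pheno)

    age_c = pheno["age"].to_numpy() - spec.age_mean
    tbv_c = pheno["tbv"].to_numpy() - spec.tbv_mean
    true_z = np.tile(baseline_z, (n_sub, 1))
    true_z += (spec.age_z_slope * age_c + spec.tbv_z_slope * tbv_c)[:, None]
    true_z += rng.normal(0.0, spec.subject_z_sd, size=(n_sub, n_edges))
    for edge, (b, s_res) in slopes.items():
        true_z[:, edge_idx[edge]] += b * s_res
    group = pheno["group"].to_numpy()
    for edge, g, dz in spec.group_effect_edges:
        true_z[group == g, edge_idx[edge]] += dz

    iu = np.triu_indices(spec.n_networks, k=1)
    runs = {}
    for i, sid in enumerate(pheno["subject_id"]):
        R = np.eye(spec.n_networks)
        R[iu] = np.tanh(true_z[i])
        R = R + np.triu(R, 1).T
        R = nearest_pd_correlation(R)
        L = np.linalg.cholesky(R)
        subj_runs = []
        for k in range(spec.n_runs):
            X = rng.standard_normal((spec.n_volumes, spec.n_networks)) @ L.T
            subj_runs.append(
                ParcellatedRun(
                    subject_id=sid,
                    run_id=f"run-{k + 1}",
                    data=X,
                    motion=traces[sid][k],
                    tr_seconds=spec.tr_seconds,
                    labels=labels,
                )
            )
        runs[sid] = subj_runs

    truth = pheno[
        ["subject_id", "group", spec.score_name, "age", "sex", "tbv",
         "education", "mean_motion"]
    ].copy()
    truth = pd.concat(
        [truth, pd.DataFrame(true_z, columns=[f"true_z[{e}]" for e in elabels],
                             index=truth.index)],
        axis=1,
    )
    for edge, rho in spec.effect_edges:
        truth[f"planted_r[{edge}]"] = rho
    return runs, pheno, truth
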