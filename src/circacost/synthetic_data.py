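"""Synthetic circadian expression data with known ground truth.

The generator emulates the design of a multi-organ circadian expression
atlas: cosine oscillations sampled every two hours over two days, a
log-linear coupling between a gene's baseline expression (mesor) and its
oscillation amplitude, a tunable fraction of rhythmic genes whose
assignment is biased toward highly expressed genes, multiplicative
lognormal measurement noise, multi-organ membership of rhythmic genes,
and per-transcript sequence models (region base counts, decay rates).

Amplitude model
---------------
For rhythmic gene g with mesor m_g:

    x_g(t) = m_g * (1 + (A_g/m_g) * cos(2*pi*(t - phi_g)/period)) * eps_g(t)

    log A_g = c0 + b * log m_g + e_g,     e_g ~ truncated N(0, sigma_e^2)

with b = ``amplitude_mesor_slope`` fixed and sigma_e solved numerically so
that the population corr^2(log m, log A) over the realized rhythmic set
equals ``coupling_r2``. The residual is truncated so that the relative
amplitude A/m stays inside [rel_amplitude_min, rel_amplitude_max]; the
solver accounts for the truncation (its moments enter the corr^2 target),
so the planted coupling is honest rather than distorted by the clipping.
A config whose parameters imply amplitudes at or above the mesor
(rel_amplitude_max >= 1, or a median outside the allowed band) is rejected
before generation, since it would produce negative expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_expression",
    "generate_organ_panel",
    "generate_transcript_models",
    "generate_genesets",
    "generate_cost_amplitude_dataset",
]

DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(18, 65, 2))  # CT18..CT64, 24 points


@dataclass
class SimulationConfig:
    """Parameters of the synthetic circadian study.

    Defaults describe the standard conditions used throughout the test
    suite: 24 two-hourly samples over 48 h, half of the genes rhythmic with
    assignment biased toward high expression, mesor-amplitude coupling
    R^2 = 0.7 with log-log slope 1.5, median relative amplitude 0.2 and
    1.5% multiplicative noise (a replicate-averaged, low-noise regime in
    which the planted coupling is recoverable through the detection
    pipeline; noisier settings are exercised explicitly where robustness
    is the question).
    """

    n_genes: int = 2000
    timepoints: tuple = DEFAULT_TIMEPOINTS
    frac_rhythmic: float = 0.5
    period: float = 24.0
    coupling_r2: float = 0.7
    amplitude_mesor_slope: float = 1.5
    mesor_log_mean: float = 3.0
    mesor_log_sd: float = 1.0
    rel_amplitude_median: float = 0.2
    rel_amplitude_min: float = 0.0
    rel_amplitude_max: float = 0.95
    rhythmic_expression_bias: float = 2.0
    noise_cv: float = 0.015
    n_organs: int = 12
    organ_rhythm_prob: float = 0.25
    shared_gene_frac: float = 0.2
    shared_organ_prob: float = 0.8
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 5:
            raise ValueError("n_genes must be at least 5 (quintiles)")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise ValueError("frac_rhythmic must lie in [0, 1]")
        if not 0.0 <= self.coupling_r2 <= 1.0:
            raise ValueError("coupling_r2 must lie in [0, 1]")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.mesor_log_sd <= 0:
            raise ValueError("mesor_log_sd must be positive")
        if self.n_organs < 1:
            raise ValueError("n_organs must be at least 1")
        # amplitude >= mesor would mean negative expression at the trough
        if self.rel_amplitude_max >= 1.0:
            raise ValueError("rel_amplitude_max must be < 1: amplitude may "
                             "not exceed the mesor (negative expression)")
        if not 0.0 < self.rel_amplitude_median < self.rel_amplitude_max:
            raise ValueError("rel_amplitude_median must lie strictly between "
                             "0 and rel_amplitude_max")
        if not 0.0 <= self.rel_amplitude_min < self.rel_amplitude_median:
            raise ValueError("rel_amplitude_min must lie in "
                             "[0, rel_amplitude_median)")


@dataclass
class GroundTruth:
    """Per-gene truth table plus optional organ membership and gene sets.

    ``genes`` columns: gene_id, is_rhythmic, mesor, amplitude, phase,
    rel_amplitude. Non-rhythmic genes have amplitude 0 and NaN phase.
    ``organ_membership`` (genes x organs, bool) marks the organs in which a
    rhythmic gene oscillates; every rhythmic gene belongs to at least one.
    """

    genes: pd.DataFrame
    organ_membership: pd.DataFrame | None = None
    genesets: dict | None = None

    def rhythmic_ids(self):
        g = self.genes
        return g.loc[g["is_rhythmic"], "gene_id"].tolist()


# ---------------------------------------------------------------------------
# residual-variance solver
# ---------------------------------------------------------------------------

def _trunc_moments(sigma, lo, hi):
    """Mean and variance of N(0, sigma^2) truncated to [lo, hi] (elementwise)."""
    a = lo / sigma
    b = hi / sigma
    a = np.clip(a, -38, 38)
    b = np.clip(b, -38, 38)
    Z = ndtr(b) - ndtr(a)
    Z = np.maximum(Z, 1e-300)
    pa = np.exp(-0.5 * a * a) / np.sqrt(2 * np.pi)
    pb = np.exp(-0.5 * b * b) / np.sqrt(2 * np.pi)
    h = (pa - pb) / Z
    mean = sigma * h
    var = sigma**2 * np.maximum(1.0 + (a * pa - b * pb) / Z - h * h, 0.0)
    return mean, var


def _coupling_r2_at(sigma, x, slope, lo, hi):
    """Population corr^2(log mesor, log amplitude) for residual sd sigma."""
    m, v = _trunc_moments(sigma, lo, hi)
    loc = slope * x + m
    cov = np.cov(x, loc)[0, 1]
    var_a = np.var(loc, ddof=1) + np.mean(v)
    var_x = np.var(x, ddof=1)
    if var_a <= 0 or var_x <= 0:
        return 0.0
    return cov * cov / (var_x * var_a)


def _solve_residual_sd(x, slope, target_r2, lo, hi):
    """Find sigma_e such that the planted corr^2 equals target_r2."""
    if target_r2 >= 1.0:
        if np.any(lo > 0) or np.any(hi < 0):
            raise ValueError("coupling_r2 = 1 is incompatible with the "
                             "relative-amplitude bounds for this config")
        return 0.0
    f = lambda s: _coupling_r2_at(s, x, slope, lo, hi) - target_r2
    s_hi = max(abs(slope), 0.1) * np.std(x)
    if s_hi <= 0:
        s_hi = 1.0
    for _ in range(60):
        if f(s_hi) < 0:
            break
        s_hi *= 2.0
    else:
        raise ValueError("cannot reach the requested coupling_r2 under the "
                         "relative-amplitude bounds")
    return brentq(f, 1e-9, s_hi, xtol=1e-10)


def _sample_truncated(rng, sigma, lo, hi):
    """Exact inverse-CDF draw from N(0, sigma^2) truncated to [lo, hi]."""
    if sigma == 0.0:
        return np.zeros_like(lo)
    a = ndtr(np.clip(lo / sigma, -38, 38))
    b = ndtr(np.clip(hi / sigma, -38, 38))
    u = rng.uniform(size=lo.shape)
    q = np.clip(a + u * (b - a), 1e-15, 1 - 1e-15)
    return sigma * ndtri(q)


# ---------------------------------------------------------------------------
# core draws
# ---------------------------------------------------------------------------

def _gene_ids(n):
    return [f"g{k:05d}" for k in range(n)]


def _draw_mesors(cfg, rng):
    return np.exp(rng.normal(cfg.mesor_log_mean, cfg.mesor_log_sd, cfg.n_genes))


def _draw_rhythmic_mask(cfg, rng, log_mesor):
    n = cfg.n_genes
    k = int(round(cfg.frac_rhythmic * n))
    mask = np.zeros(n, dtype=bool)
    if k == 0:
        return mask
    rank = np.argsort(np.argsort(log_mesor))
    u = 2.0 * rank / max(n - 1, 1) - 1.0
    w = np.exp(cfg.rhythmic_expression_bias * u)
    idx = rng.choice(n, size=k, replace=False, p=w / w.sum())
    mask[idx] = True
    return mask


def _draw_amplitudes(cfg, rng, log_mesor, mask):
    """Amplitude and phase for rhythmic genes; zeros/NaN elsewhere."""
    n = cfg.n_genes
    amp = np.zeros(n)
    phase = np.full(n, np.nan)
    if not mask.any():
        return amp, phase
    x = log_mesor[mask]
    mu = cfg.mesor_log_mean
    b = cfg.amplitude_mesor_slope if cfg.coupling_r2 > 0 else 0.0
    c0 = np.log(cfg.rel_amplitude_median) - (b - 1.0) * mu
    # bounds on the residual keep the relative amplitude inside its band
    base = c0 + (b - 1.0) * x
    hi = np.log(cfg.rel_amplitude_max) - base
    if cfg.rel_amplitude_min > 0:
        lo = np.log(cfg.rel_amplitude_min) - base
    else:
        lo = np.full_like(hi, -np.inf)
    if cfg.coupling_r2 > 0:
        sigma = _solve_residual_sd(x, b, cfg.coupling_r2, lo, hi)
    else:
        sigma = abs(cfg.amplitude_mesor_slope) * np.std(x)
    e = _sample_truncated(rng, sigma, lo, hi)
    log_ratio = base + e
    amp[mask] = np.exp(log_ratio + x)
    phase[mask] = rng.uniform(0.0, cfg.period, size=mask.sum())
    return amp, phase


def _render_matrix(cfg, rng, mesor, mask, amp, phase):
    tp = np.asarray(cfg.timepoints, dtype=float)
    n = cfg.n_genes
    signal = np.ones((n, tp.size))
    if mask.any():
        theta = 2 * np.pi * (tp[None, :] - phase[mask, None]) / cfg.period
        signal[mask] = 1.0 + (amp[mask] / mesor[mask])[:, None] * np.cos(theta)
    values = mesor[:, None] * signal
    if cfg.noise_cv > 0:
        s = np.sqrt(np.log1p(cfg.noise_cv**2))
        values = values * np.exp(rng.normal(-0.5 * s * s, s, values.shape))
    return values


def generate_expression(cfg: SimulationConfig):
    """Generate a single-organ expression matrix with ground truth.

    Returns ``(TimeSeriesMatrix, GroundTruth)``; fully reproducible from
    ``cfg.seed``. Expression values are strictly positive by construction.
    """
    from .rhythm_detection import TimeSeriesMatrix

    rng = np.random.default_rng(cfg.seed)
    mesor = _draw_mesors(cfg, rng)
    log_mesor = np.log(mesor)
    mask = _draw_rhythmic_mask(cfg, rng, log_mesor)
    amp, phase = _draw_amplitudes(cfg, rng, log_mesor, mask)
    values = _render_matrix(cfg, rng, mesor, mask, amp, phase)
    genes = pd.DataFrame({
        "gene_id": _gene_ids(cfg.n_genes),
        "is_rhythmic": mask,
        "mesor": mesor,
        "amplitude": amp,
        "phase": phase,
        "rel_amplitude": np.where(mask, amp / mesor, 0.0),
    })
    matrix = TimeSeriesMatrix(genes["gene_id"].tolist(),
                              np.asarray(cfg.timepoints, float), values)
    return matrix, GroundTruth(genes=genes)


def generate_organ_panel(cfg: SimulationConfig):
    """Generate one matrix per organ with shared mesors/amplitudes.

    A gene rhythmic anywhere gets an organ membership set via independent
    Bernoulli draws; a ``shared_gene_frac`` subset of broadly rhythmic genes
    uses the higher ``shared_organ_prob``. Every rhythmic gene oscillates in
    at least one organ. Noise is drawn independently per organ.

    Returns ``(dict organ_name -> TimeSeriesMatrix, GroundTruth)``.
    """
    from .rhythm_detection import TimeSeriesMatrix

    rng = np.random.default_rng(cfg.seed)
    mesor = _draw_mesors(cfg, rng)
    log_mesor = np.log(mesor)
    mask = _draw_rhythmic_mask(cfg, rng, log_mesor)
    amp, phase = _draw_amplitudes(cfg, rng, log_mesor, mask)

    organs = [f"organ_{k + 1:02d}" for k in range(cfg.n_organs)]
    member = np.zeros((cfg.n_genes, cfg.n_organs), dtype=bool)
    ridx = np.flatnonzero(mask)
    if ridx.size:
        shared = rng.uniform(size=ridx.size) < cfg.shared_gene_frac
        prob = np.where(shared, cfg.shared_organ_prob, cfg.organ_rhythm_prob)
        member[ridx] = rng.uniform(size=(ridx.size, cfg.n_organs)) < prob[:, None]
        empty = ridx[~member[ridx].any(axis=1)]
        if empty.size:
            member[empty, rng.integers(0, cfg.n_organs, size=empty.size)] = True

    matrices = {}
    for o, organ in enumerate(organs):
        organ_mask = mask & member[:, o]
        values = _render_matrix(cfg, rng, mesor, organ_mask, amp, phase)
        matrices[organ] = TimeSeriesMatrix(_gene_ids(cfg.n_genes),
                                           np.asarray(cfg.timepoints, float),
                                           values)

    genes = pd.DataFrame({
        "gene_id": _gene_ids(cfg.n_genes),
        "is_rhythmic": mask,
        "mesor": mesor,
        "amplitude": amp,
        "phase": phase,
        "rel_amplitude": np.where(mask, amp / mesor, 0.0),
    })
    membership = pd.DataFrame(member, index=genes["gene_id"], columns=organs)
    return matrices, GroundTruth(genes=genes, organ_membership=membership)


# ---------------------------------------------------------------------------
# transcript models, gene sets, planted cost-amplitude data
# ---------------------------------------------------------------------------

def generate_transcript_models(cfg: SimulationConfig, truth: GroundTruth | None = None,
                               utr5_range=(50, 300), cds_range=(300, 3000),
                               utr3_range=(100, 2000), dirichlet_alpha=(1.0, 1.0, 1.0, 1.0),
                               decay_log_median=np.log(0.1), decay_log_sd=0.5):
    """One sequence model per gene: region base counts and a decay rate.

    Region lengths are uniform integers in the configured ranges, base
    compositions Dirichlet-distributed (counts multinomial at the drawn
    composition), decay rates lognormal per hour (default median 0.1/h,
    i.e. a ~7 h half-life). Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_genes
    ids = truth.genes["gene_id"].tolist() if truth is not None else _gene_ids(n)
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if np.any(alpha < 0) or not np.any(alpha > 0):
        raise ValueError("dirichlet_alpha entries must be non-negative with "
                         "at least one positive")
    live = alpha > 0  # zero concentration = structurally absent base
    cols = {"transcript_id": ids}
    for region, (lo, hi) in (("5", utr5_range), ("C", cds_range), ("3", utr3_range)):
        lengths = rng.integers(lo, hi + 1, size=n)
        props = np.zeros((n, 4))
        props[:, live] = rng.dirichlet(alpha[live], size=n)
        counts = np.array([rng.multinomial(L, p) for L, p in zip(lengths, props)])
        for b_idx, base in enumerate("acgu"):
            cols[f"{base}{region}"] = counts[:, b_idx]
    cols["decay_rate"] = np.exp(rng.normal(decay_log_median, decay_log_sd, n))
    return pd.DataFrame(cols)


def generate_genesets(truth: GroundTruth, n_sets=50, size_range=(10, 100),
                      expression_bias=0.0, seed=0):
    """Gene-set collection over the simulated universe.

    With ``expression_bias > 0`` membership probability increases with the
    mesor rank, planting the expression confounding that makes highly
    expressed pathways look over-enriched among cycling genes; bias 0 gives
    uniform sampling.
    """
    genes = truth.genes
    n = len(genes)
    lo, hi = size_range
    if not (2 <= lo <= hi <= n):
        raise ValueError("size_range must lie within [2, n_genes]")
    rng = np.random.default_rng(seed)
    rank = np.argsort(np.argsort(genes["mesor"].to_numpy()))
    u = 2.0 * rank / max(n - 1, 1) - 1.0
    w = np.exp(expression_bias * u)
    p = w / w.sum()
    ids = genes["gene_id"].to_numpy()
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(ids, size=size, replace=False, p=p)
        sets[f"set_{k + 1:03d}"] = sorted(members.tolist())
    return sets


def generate_cost_amplitude_dataset(n, rho=0.7, target_r2=0.5, seed=0, null=False):
    """Planted benchmark for the variance-partition stage.

    Three log region costs with population equicorrelation ``rho`` share a
    common factor; log amplitude is their mean plus independent noise scaled
    so that the population R^2 of amplitude on the three costs equals
    ``target_r2``. With ``null=True`` the amplitude is independent noise of
    the same marginal variance.

    Returns ``(log_costs (n, 3), log_amplitude (n,))``.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n)
    costs = (np.sqrt(rho) * f[:, None]
             + np.sqrt(1 - rho) * rng.normal(size=(n, 3)))
    lin = costs.mean(axis=1)
    var_lin = (1 + 2 * rho) / 3.0
    noise_sd = np.sqrt(var_lin * (1 - target_r2) / target_r2)
    if null:
        amp = rng.normal(scale=np.sqrt(var_lin / target_r2), size=n)
    else:
        amp = lin + rng.normal(scale=noise_sd, size=n)
    return costs, amp
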