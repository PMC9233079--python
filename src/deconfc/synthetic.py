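"""Synthetic cohorts for exercising the deconfounding pipeline.

Two generators are provided.  The *toy* cohort is a minimal
missing-outcome problem with a known closed-form truth: diagnosis A,
a single severity covariate ``W_c`` that is exactly zero in the
typically developing (TD) group and lognormal in the ASD group, nine
standard-normal nuisance covariates, a logistic usability mechanism
driven by severity, and a linear outcome.  Because severity lowers
both the probability of a usable scan and the outcome, the usable-case
(naive) group difference is biased toward zero and the bias is
removable given the covariates — the textbook selection-bias setting.

The *cohort* generator emulates a realistic developmental sample:
phenotypes whose distributions differ by diagnosis, motion traces whose
amplitude increases with symptom severity and decreases with age and
cognitive ability, scan usability obtained by running the motion-QC
rules on those traces, and edgewise connectivity outcomes that depend
on phenotypes and diagnosis.  It produces everything the full pipeline
consumes; none of its parameter values are estimates from real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import expit

__all__ = [
    "ToyParams",
    "ToyTruth",
    "CohortConfig",
    "generate_toy_cohort",
    "toy_truth",
    "generate_motion_trace",
    "generate_component_timecourses",
    "generate_cohort",
]


@dataclass(frozen=True)
class ToyParams:
    """Parameters of the toy selection-bias generative model.

    Defaults give ~25% ASD prevalence, ~88%/~60% usable data in the
    TD/ASD groups, pooled corr(W_c, Y) ~ -0.56 and a between-group
    Cohen's d ~ 0.51.
    """

    n: int = 550
    p_asd: float = 0.25
    severity_logmean: float = 2.0
    severity_logsd: float = 0.4
    propensity_intercept: float = 2.0
    propensity_slope: float = -0.2
    outcome_slope_wc: float = -0.2
    outcome_intercept_td: float = 0.0
    outcome_intercept_asd: float = 1.4
    n_noise_covariates: int = 9
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not 0.0 < self.p_asd < 1.0:
            raise ValueError(f"p_asd must be in (0, 1), got {self.p_asd}")
        if self.severity_logsd <= 0:
            raise ValueError("severity_logsd must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_noise_covariates < 0:
            raise ValueError("n_noise_covariates must be >= 0")


@dataclass(frozen=True)
class ToyTruth:
    """Population quantities of the toy model (quadrature/closed form)."""

    mean_asd: float          # E*[Y(1) | A=1], counterfactual all-usable
    mean_td: float           # E*[Y(1) | A=0]
    p_usable_asd: float      # P(Delta=1 | A=1)
    p_usable_td: float       # P(Delta=1 | A=0)
    cohens_d: float          # |mean_td - mean_asd| / weighted pooled sd
    corr_wc_y: float         # pooled Pearson corr(W_c, Y)
    naive_mean_asd: float    # E[Y | Delta=1, A=1] (selection-biased)


def generate_toy_cohort(params: ToyParams) -> pd.DataFrame:
    """Draw a toy cohort of ``params.n`` i.i.d. participants.

    Returns a DataFrame with columns ``A`` (diagnosis), ``W_c``
    (severity; exactly 0 for TD), ``W_1..W_k`` nuisance covariates,
    ``delta`` (usability) and ``Y`` (outcome, NaN where delta == 0).
    ``Y_complete`` carries the counterfactual all-usable outcome for
    every row — known only because the generator is synthetic; it is
    what the deconfounded estimator tries to recover the mean of.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    a = rng.binomial(1, params.p_asd, size=n)
    w_c = np.where(
        a == 1,
        rng.lognormal(params.severity_logmean, params.severity_logsd, size=n),
        0.0,
    )
    noise_w = rng.standard_normal((n, params.n_noise_covariates))
    g = expit(params.propensity_intercept + params.propensity_slope * w_c)
    delta = rng.binomial(1, g)
    mu = (
        np.where(a == 1, params.outcome_intercept_asd, params.outcome_intercept_td)
        + params.outcome_slope_wc * w_c
    )
    y_complete = mu + params.noise_sd * rng.standard_normal(n)
    y = np.where(delta == 1, y_complete, np.nan)

    out = pd.DataFrame({"A": a, "W_c": w_c})
    for j in range(params.n_noise_covariates):
        out[f"W_{j + 1}"] = noise_w[:, j]
    out["delta"] = delta
    out["Y"] = y
    out["Y_complete"] = y_complete
    return out


def toy_truth(params: ToyParams) -> ToyTruth:
    """Analytic truth for the toy model.

    Uses the lognormal mean exp(logmean + logsd^2/2) for the
    counterfactual means and Gaussian quadrature over the severity
    distribution for usability and the usable-case (naive) mean.
    """
    m, s = params.severity_logmean, params.severity_logsd
    ln_mean = np.exp(m + s**2 / 2.0)
    ln_var = (np.exp(s**2) - 1.0) * np.exp(2.0 * m + s**2)

    mean_asd = params.outcome_intercept_asd + params.outcome_slope_wc * ln_mean
    mean_td = params.outcome_intercept_td

    dist = stats.lognorm(s=s, scale=np.exp(m))
    prop = lambda w: expit(params.propensity_intercept + params.propensity_slope * w)
    p_usable_asd, _ = integrate.quad(lambda w: prop(w) * dist.pdf(w), 0, np.inf)
    p_usable_td = float(expit(params.propensity_intercept))

    # E[W_c | Delta=1, A=1] by quadrature -> selection-biased ASD mean
    num, _ = integrate.quad(lambda w: w * prop(w) * dist.pdf(w), 0, np.inf)
    naive_mean_asd = (
        params.outcome_intercept_asd + params.outcome_slope_wc * num / p_usable_asd
    )

    # group-size-weighted pooled variance; W_c contributes only in ASD
    p1 = params.p_asd
    var_td = params.noise_sd**2
    var_asd = params.noise_sd**2 + params.outcome_slope_wc**2 * ln_var
    pooled_var = (1 - p1) * var_td + p1 * var_asd
    cohens_d = abs(mean_td - mean_asd) / np.sqrt(pooled_var)

    # pooled corr(W_c, Y) with W_c = A * L, L ~ lognormal
    e_l, e_l2 = ln_mean, ln_var + ln_mean**2
    b, c1, c0 = params.outcome_slope_wc, params.outcome_intercept_asd, params.outcome_intercept_td
    e_wc = p1 * e_l
    e_y = (1 - p1) * c0 + p1 * (c1 + b * e_l)
    e_wcy = p1 * (c1 * e_l + b * e_l2)
    var_wc = p1 * e_l2 - e_wc**2
    e_m = c1 + b * e_l
    e_m2 = c1**2 + 2 * c1 * b * e_l + b**2 * e_l2
    var_y = (
        (1 - p1) * c0**2 + p1 * e_m2 - ((1 - p1) * c0 + p1 * e_m) ** 2
        + params.noise_sd**2
    )
    corr = (e_wcy - e_wc * e_y) / np.sqrt(var_wc * var_y)

    return ToyTruth(
        mean_asd=float(mean_asd),
        mean_td=float(mean_td),
        p_usable_asd=float(p_usable_asd),
        p_usable_td=p_usable_td,
        cohens_d=float(cohens_d),
        corr_wc_y=float(corr),
        naive_mean_asd=float(naive_mean_asd),
    )


# ---------------------------------------------------------------------------
# motion traces and component timecourses
# ---------------------------------------------------------------------------

def generate_motion_trace(
    n_frames: int,
    tr: float = 2.5,
    walk_sd: float = 0.02,
    spike_rate: float = 0.0,
    spike_scale: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate a 6-column rigid-body realignment trace.

    Columns are x, y, z translations (mm) then pitch, roll, yaw
    rotations (rad).  The process is a Gaussian random walk in each
    parameter (per-frame increment sd ``walk_sd`` mm, and ``walk_sd/50``
    rad so translations and arc length at a 50 mm radius contribute
    comparably), plus sporadic transient spikes occurring independently
    per frame with probability ``spike_rate`` and exponential magnitude
    ``spike_scale`` mm.  This is a plausibility model for head motion,
    not a fit to any dataset.
    """
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    if tr <= 0:
        raise ValueError(f"tr must be > 0, got {tr}")
    if walk_sd < 0 or spike_rate < 0:
        raise ValueError("walk_sd and spike_rate must be >= 0")
    rng = np.random.default_rng(seed)
    scale = np.array([1.0, 1.0, 1.0, 1 / 50.0, 1 / 50.0, 1 / 50.0])
    steps = rng.standard_normal((n_frames, 6)) * walk_sd * scale
    steps[0] = 0.0
    if spike_rate > 0:
        hit = rng.random(n_frames) < spike_rate
        hit[0] = False
        mag = rng.exponential(spike_scale, size=(n_frames, 6)) * scale
        sign = rng.choice([-1.0, 1.0], size=(n_frames, 6))
        spikes = np.where(hit[:, None], mag * sign, 0.0)
        # transient: displace one frame, return on the next
        trace = np.cumsum(steps, axis=0) + spikes
    else:
        trace = np.cumsum(steps, axis=0)
    return trace


def generate_component_timecourses(
    precision: np.ndarray, n_frames: int, seed: int | None = None
) -> np.ndarray:
    """Sample Gaussian component timecourses with a planted precision.

    Returns an ``n_frames x K`` matrix drawn from N(0, precision^-1);
    the partial-correlation structure of the sample converges to
    -theta_ij / sqrt(theta_ii theta_jj) of the planted matrix.
    """
    precision = np.asarray(precision, dtype=float)
    if precision.ndim != 2 or precision.shape[0] != precision.shape[1]:
        raise ValueError("precision must be square")
    if not np.allclose(precision, precision.T, atol=1e-10):
        raise ValueError("precision must be symmetric")
    eigvals = np.linalg.eigvalsh(precision)
    if eigvals.min() <= 0:
        raise ValueError("precision must be positive definite")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(precision)
    return rng.multivariate_normal(
        np.zeros(precision.shape[0]), cov, size=n_frames, method="cholesky"
    )


# ---------------------------------------------------------------------------
# developmental cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic developmental cohort.

    Phenotype distributions differ by diagnosis (higher symptom scores
    and slightly lower GAI in the ASD group); the per-subject motion
    random-walk amplitude rises with ADOS, inattention, hyperactivity
    and motor overflow and falls with age and GAI through
    ``motion_coefs`` on standardized phenotypes; edgewise connectivity
    means shift with diagnosis and phenotypes through per-edge
    coefficients drawn once from ``seed``.
    """

    n: int = 300
    p_asd: float = 0.3
    n_edges: int = 20
    n_frames: int = 128
    tr: float = 2.5
    # baseline log motion amplitude (mm) and phenotype loadings,
    # chosen so the QC rules exclude roughly one in six TD and one in
    # four ASD scans (lenient) and the majority of scans (strict)
    log_amp_mean: float = np.log(0.045)
    log_amp_sd: float = 0.45
    motion_coefs: dict = field(
        default_factory=lambda: {
            "ados": 0.20,
            "inattention": 0.08,
            "hyperactivity": 0.12,
            "motor_overflow": 0.08,
            "age": -0.15,
            "gai": -0.08,
        }
    )
    spike_rate: float = 0.002
    # edge model: per-edge effects ~ N(0, sd) for diagnosis and phenotypes
    edge_diag_sd: float = 0.08
    edge_pheno_sd: float = 0.04
    edge_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not 0 < self.p_asd < 1:
            raise ValueError("p_asd must be in (0,1)")
        if self.n_edges < 1:
            raise ValueError("n_edges must be >= 1")
        if min(self.log_amp_sd, self.edge_noise_sd) <= 0:
            raise ValueError("variance parameters must be > 0")


#: phenotypes entering the propensity/outcome predictor block
PHENOTYPES = (
    "age", "handedness", "secondary_adhd", "stimulant",
    "motor_overflow", "gai", "inattention", "hyperactivity", "ados",
)
#: covariates reserved for the edgewise adjustment model
ADJUSTMENT_COVARIATES = ("sex", "race", "ses")


def generate_cohort(config: CohortConfig):
    """Generate a synthetic developmental cohort.

    Returns ``(subjects, traces, edges)``: a phenotype table (one row
    per participant), a list of realignment traces, and an
    ``n x n_edges`` array of Fisher-z edge outcomes for every subject
    (downstream code masks rows failing QC).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    a = rng.binomial(1, config.p_asd, size=n)

    age = rng.uniform(8.0, 13.0, size=n)
    gai = np.round(rng.normal(np.where(a == 1, 104.0, 112.0), 12.0))
    srs = np.clip(np.round(rng.normal(np.where(a == 1, 75.0, 42.0), 12.0)), 0, None)
    ados = np.where(a == 1, np.round(rng.lognormal(2.4, 0.35, size=n)), 0.0)
    inatt = np.clip(np.round(rng.normal(np.where(a == 1, 14.0, 6.0), 5.0)), 0, 27)
    hyper = np.clip(np.round(rng.normal(np.where(a == 1, 11.0, 5.0), 5.0)), 0, 27)
    overflow = np.clip(rng.normal(np.where(a == 1, 20.0, 12.0), 7.0), 0, None)
    handed = rng.choice(["right", "left", "mixed"], size=n, p=[0.82, 0.08, 0.10])
    adhd = rng.binomial(1, np.where(a == 1, 0.45, 0.12))
    stim = rng.binomial(1, np.where(adhd == 1, 0.5, 0.03))
    sex = rng.choice(["M", "F"], size=n, p=[0.65, 0.35])
    race = rng.choice(
        ["AfricanAmerican", "Caucasian", "Other"], size=n, p=[0.25, 0.6, 0.15]
    )
    ses = np.round(rng.normal(50.0, 10.0, size=n))

    subjects = pd.DataFrame({
        "A": a, "age": age, "handedness": handed, "secondary_adhd": adhd,
        "stimulant": stim, "motor_overflow": overflow, "gai": gai,
        "inattention": inatt, "hyperactivity": hyper, "ados": ados,
        "srs": srs, "sex": sex, "race": race, "ses": ses,
    })

    # standardized phenotype block drives motion amplitude and edges
    pheno_cols = ["ados", "inattention", "hyperactivity", "motor_overflow", "age", "gai"]
    z = subjects[pheno_cols].to_numpy(float)
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    coefs = np.array([config.motion_coefs.get(c, 0.0) for c in pheno_cols])
    log_amp = (
        config.log_amp_mean
        + z @ coefs
        + config.log_amp_sd * rng.standard_normal(n)
    )
    amps = np.exp(log_amp)
    traces = [
        generate_motion_trace(
            config.n_frames, config.tr, walk_sd=amps[i],
            spike_rate=config.spike_rate * (amps[i] / np.exp(config.log_amp_mean)),
            seed=int(rng.integers(2**31 - 1)),
        )
        for i in range(n)
    ]

    beta_diag = rng.normal(0.0, config.edge_diag_sd, size=config.n_edges)
    beta_pheno = rng.normal(0.0, config.edge_pheno_sd, size=(len(pheno_cols), config.n_edges))
    edges = (
        0.1
        + np.outer(a, beta_diag)
        + z @ beta_pheno
        + config.edge_noise_sd * rng.standard_normal((n, config.n_edges))
    )
    return subjects, traces, edges
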