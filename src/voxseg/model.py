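"""Hierarchical Gamma–Poisson expression model and its Gibbs updates.

Transcripts are modelled as a Poisson point process whose intensity for
gene g at a point is the sum of a spatially constant background rate
τ_g^bg and the rate τ_gc of the cell owning the containing voxel (zero in
unassigned space). Per-cell rates follow a k-component Gamma mixture,

    τ_gc ~ Gamma(α_{g,z_c}, β_{g,z_c}),   z_c ~ Categorical(π),

so per-cell counts are marginally negative binomial, which is what makes
the conjugate augmentation updates below possible: a Chinese-restaurant-
table (CRT) draw gives a Gamma update for the shapes α, and Polya-Gamma
draws give a Normal update for φ = −log β. Cell volumes are LogNormal by
component, and an optional "nuclear prior" rewards keeping transcripts on
their initial nuclear assignment.

All updates are exact conditional draws; `gibbs_sweep` chains them into
one full parameter sweep with cell boundaries held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

DEFAULT_P_NUC = 0.8  # prior probability that a nuclear assignment is correct


@dataclass
class PriorConfig:
    """Hyperparameters of the expression, volume and nuclear priors.

    Defaults are implementation choices (weakly informative), except
    ``p_nuc`` and the Dirichlet(1) component prior.
    """

    k: int = 10
    e0bg: float = 1.0
    f0bg: float = 1.0
    e0: float = 1.0
    f0: float = 1.0
    gamma: float = 1.0  # precision of the Normal prior on φ = −log β
    p_nuc: float = DEFAULT_P_NUC
    mu0: float = float(np.log(200.0))  # prior mean of log cell volume (μm³)
    sigma0: float = 1.0  # prior precision on μ_t
    alpha0: float = 1.0  # Gamma prior shape on the log-volume precision
    beta0: float = 1.0  # Gamma prior rate on the log-volume precision
    dirichlet_conc: float = 1.0
    resample_pi: bool = True

    def __post_init__(self):
        if not (0.0 < self.p_nuc < 1.0):
            raise ValueError("p_nuc must lie in (0, 1)")
        for name in ("e0bg", "f0bg", "e0", "f0", "gamma", "sigma0", "alpha0", "beta0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class CountMatrix:
    """Per-gene-per-cell non-background counts plus background counts."""

    X: np.ndarray  # (m, n) int64
    X_bg: np.ndarray  # (m,) int64

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def M(self) -> int:
        return int(self.X.sum() + self.X_bg.sum())

    @classmethod
    def from_assignments(cls, gene: np.ndarray, cell: np.ndarray, m: int, n: int):
        """Build counts from per-transcript gene ids and cell assignments
        (cell < 0 means background)."""
        gene = np.asarray(gene)
        cell = np.asarray(cell)
        bg = cell < 0
        X = np.zeros((m, n), dtype=np.int64)
        if (~bg).any():
            np.add.at(X, (gene[~bg], cell[~bg]), 1)
        X_bg = np.bincount(gene[bg], minlength=m).astype(np.int64)
        return cls(X, X_bg)


@dataclass
class ModelParams:
    """Current values of every model parameter.

    ``tau`` is (m, n): per-gene, per-cell Poisson rates (transcripts/μm³);
    ``alpha``/``phi`` are (m, k) per-component; ``z`` the per-cell
    component labels; ``mu_vol``/``prec_vol`` the per-component LogNormal
    volume parameters (precision parameterization).
    """

    tau_bg: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    phi: np.ndarray
    h: float
    pi: np.ndarray
    z: np.ndarray
    mu_vol: np.ndarray
    prec_vol: np.ndarray

    @property
    def beta(self) -> np.ndarray:
        return np.exp(-self.phi)

    @property
    def k(self) -> int:
        return self.alpha.shape[1]

    @classmethod
    def initial(cls, m: int, n: int, prior: PriorConfig, rng: np.random.Generator):
        k = prior.k
        return cls(
            tau_bg=np.full(m, 1e-4),
            tau=np.full((m, n), 1e-3),
            alpha=np.ones((m, k)),
            phi=np.zeros((m, k)),
            h=1.0,
            pi=np.full(k, 1.0 / k),
            z=rng.integers(0, k, size=n),
            mu_vol=np.full(k, prior.mu0),
            prec_vol=np.ones(k),
        )


@dataclass
class AugmentedState:
    """Auxiliary variables of the most recent sweep (diagnostics only)."""

    crt_counts: np.ndarray | None = None  # (m, n)
    omega: np.ndarray | None = None  # (m, n)


# ---------------------------------------------------------------------------
# likelihood


def log_likelihood(
    volumes: np.ndarray, counts: CountMatrix, params: ModelParams, total_volume: float
) -> float:
    """Poisson point-process log likelihood of the current segmentation.

    Includes the background exposure of unassigned space, so that the
    exposure terms sum to τ^bg over the whole lattice plus per-cell
    exposures of the cell rates.
    """
    nu = np.asarray(volumes, dtype=float)
    rates = params.tau_bg[:, None] + params.tau  # (m, n)
    ll = -float((nu[None, :] * rates).sum())
    ll -= float(params.tau_bg.sum() * (total_volume - nu.sum()))
    with np.errstate(divide="ignore"):
        point = np.where(counts.X > 0, counts.X * np.log(rates), 0.0)
        point_bg = np.where(counts.X_bg > 0, counts.X_bg * np.log(params.tau_bg), 0.0)
    if np.isneginf(point[counts.X > 0]).any() or np.isneginf(point_bg[counts.X_bg > 0]).any():
        return -np.inf
    return ll + float(point.sum()) + float(point_bg.sum())


def delta_log_likelihood(
    voxel_genes: np.ndarray,
    old_cell: int,
    new_cell: int,
    voxel_volume: float,
    params: ModelParams,
) -> float:
    """Log-likelihood change from flipping one voxel (with the listed
    transcript genes inside it) from ``old_cell`` to ``new_cell``
    (-1 = unassigned). Background exposure over the whole lattice is
    constant, so only the flipped cells' terms enter."""
    d = 0.0
    if old_cell >= 0:
        d += voxel_volume * params.tau[:, old_cell].sum()
    if new_cell >= 0:
        d -= voxel_volume * params.tau[:, new_cell].sum()
    if len(voxel_genes):
        g = np.asarray(voxel_genes)
        old_r = params.tau_bg[g] + (params.tau[g, old_cell] if old_cell >= 0 else 0.0)
        new_r = params.tau_bg[g] + (params.tau[g, new_cell] if new_cell >= 0 else 0.0)
        with np.errstate(divide="ignore"):
            d += float(np.log(new_r).sum() - np.log(old_r).sum())
    return d


def volume_log_prior(nu: float, mu: float, prec: float) -> float:
    """LogNormal(μ, precision) log density at volume ν (μm³)."""
    if nu <= 0:
        raise ValueError("cell volume must be positive")
    lv = np.log(nu)
    return float(-lv + 0.5 * np.log(prec / (2.0 * np.pi)) - 0.5 * prec * (lv - mu) ** 2)


def nuclear_log_prior_ratio(
    old_cell: int, new_cell: int, nuclear_label: int, p_nuc: float = DEFAULT_P_NUC
) -> float:
    """Log prior ratio for moving one transcript between assignments.

    Matching the nuclear label has probability p_nuc; all alternatives
    share the remainder, so the ratio between two non-matching
    assignments is 1 and the ratio only moves when the nuclear label is
    gained or lost.
    """
    if nuclear_label < 0 or old_cell == new_cell:
        return 0.0
    L = np.log(p_nuc) - np.log1p(-p_nuc)
    d = 0.0
    if new_cell == nuclear_label:
        d += L
    if old_cell == nuclear_label:
        d -= L
    return float(d)


# ---------------------------------------------------------------------------
# augmentation samplers


def sample_crt(n, r, rng: np.random.Generator) -> np.ndarray:
    """Chinese-restaurant-table draw(s): ℓ = Σ_{i=1..n} Bern(r/(r+i-1)).

    ``n`` (counts) and ``r`` (positive concentration) broadcast.
    """
    n = np.asarray(n)
    r = np.asarray(r, dtype=float)
    if np.any(n < 0):
        raise ValueError("CRT counts must be non-negative")
    n_b, r_b = np.broadcast_arrays(n, r)
    out = np.zeros(n_b.shape, dtype=np.int64)
    nmax = int(n_b.max(initial=0))
    for i in range(1, nmax + 1):
        active = n_b >= i
        if not active.any():
            break
        p = r_b[active] / (r_b[active] + i - 1.0)
        out[active] += rng.random(int(active.sum())) < p
    return out


_PG_TRUNC = 200


def sample_polya_gamma(b_par, c_par, rng: np.random.Generator, trunc: int = _PG_TRUNC):
    """Polya-Gamma draw(s) PG(b, c) via the sum-of-Gammas representation

        ω = (1/2π²) Σ_k g_k / ((k-1/2)² + c²/(4π²)),  g_k ~ Gamma(b, 1),

    truncated at ``trunc`` terms with the omitted tail replaced by its
    expectation, which makes E[ω] exact at every shape. Broadcasts over
    ``b_par`` and ``c_par``.
    """
    b = np.asarray(b_par, dtype=float)
    c = np.asarray(c_par, dtype=float)
    if np.any(b <= 0):
        raise ValueError("Polya-Gamma shape must be positive")
    b_b, c_b = np.broadcast_arrays(b, c)
    shape = b_b.shape
    a = np.abs(c_b) / (2.0 * np.pi)
    k = np.arange(1, trunc + 1, dtype=float)
    denom = (k - 0.5) ** 2  # (trunc,)
    d = denom.reshape((trunc,) + (1,) * len(shape)) + a**2
    if b_b.size and np.ptp(b_b) == 0:  # constant shape: scalar fast path
        g = rng.standard_gamma(float(b_b.flat[0]), size=d.shape)
    else:
        g = rng.standard_gamma(np.broadcast_to(b_b, d.shape))
    partial = (g / d).sum(axis=0)
    # exact Σ_k 1/((k-1/2)² + a²) = π tanh(πa) / (2a), limit π²/2 at a=0
    with np.errstate(divide="ignore", invalid="ignore"):
        full = np.where(a > 1e-12, np.pi * np.tanh(np.pi * a) / (2.0 * a), np.pi**2 / 2.0)
    tail = b_b * (full - (1.0 / d).sum(axis=0))
    omega = (partial + tail) / (2.0 * np.pi**2)
    if shape == ():
        return float(omega)
    return omega


def pg_mean(b, c):
    """Closed-form PG mean (b/2c)·tanh(c/2), with the b/4 limit at c=0."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(np.abs(c) > 1e-12, b / (2.0 * c) * np.tanh(c / 2.0), b / 4.0)


# ---------------------------------------------------------------------------
# Gibbs updates


def nb_logpmf(x, alpha, log_beta_ratio, log_nu_ratio):
    """log NB(x; α, ν/(ν+β)) up to terms constant in the component.

    ``log_beta_ratio`` = log(β/(ν+β)) and ``log_nu_ratio`` = log(ν/(ν+β)).
    """
    return gammaln(x + alpha) - gammaln(alpha) + alpha * log_beta_ratio + x * log_nu_ratio


def sample_component_assignments(
    counts: CountMatrix,
    volumes: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw z_c with P(z_c = t) ∝ π_t Π_g NB(X_gc; α_gt, ν_c/(ν_c+β_gt))."""
    X = counts.X
    nu = np.asarray(volumes, dtype=float)
    k = params.k
    logw = np.empty((k, counts.n))
    for t in range(k):
        alpha_t = params.alpha[:, t][:, None]  # (m, 1)
        beta_t = params.beta[:, t][:, None]
        lbr = np.log(beta_t) - np.log(nu[None, :] + beta_t)
        lnr = np.log(nu[None, :]) - np.log(nu[None, :] + beta_t)
        logw[t] = np.log(params.pi[t]) + nb_logpmf(X, alpha_t, lbr, lnr).sum(axis=0)
    if not np.isfinite(logw.max(axis=0)).all():
        raise FloatingPointError("all component weights are -inf for some cell")
    gumb = rng.gumbel(size=logw.shape)
    z = np.argmax(logw + gumb, axis=0)
    params.z = z
    return z


def sample_rates(
    counts: CountMatrix,
    volumes: np.ndarray,
    params: ModelParams,
    prior: PriorConfig,
    total_volume: float,
    rng: np.random.Generator,
) -> None:
    """Conjugate Gamma draws for per-cell rates and the background rate.

    The background is active over the entire lattice, so its exposure is
    the total lattice volume.
    """
    nu = np.asarray(volumes, dtype=float)
    a_cell = params.alpha[:, params.z]  # (m, n)
    b_cell = params.beta[:, params.z]
    params.tau = rng.gamma(a_cell + counts.X) / (b_cell + nu[None, :])
    params.tau_bg = rng.gamma(prior.e0bg + counts.X_bg) / (prior.f0bg + total_volume)


def sample_alpha_and_h(
    counts: CountMatrix,
    volumes: np.ndarray,
    params: ModelParams,
    prior: PriorConfig,
    rng: np.random.Generator,
    aug: AugmentedState | None = None,
) -> None:
    """CRT-augmented Gamma update for the shapes α, then the shared
    hyper-rate h (which sets the overall dispersion across components)."""
    nu = np.asarray(volumes, dtype=float)
    m, n = counts.X.shape
    k = params.k
    alpha_cell = params.alpha[:, params.z]
    ell = sample_crt(counts.X, alpha_cell, rng)  # (m, n)
    if aug is not None:
        aug.crt_counts = ell
    beta_cell = params.beta[:, params.z]
    # log((ν_c + β)/β) per (g, c); each term positive
    pos = np.log1p(nu[None, :] / beta_cell)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), params.z] = 1.0
    L = ell @ onehot  # (m, k) Σ_{c∈C_t} ℓ_gc
    R = pos @ onehot  # (m, k)
    params.alpha = rng.gamma(prior.e0 + L) / (params.h + R)
    params.h = float(rng.gamma(prior.e0 + m * k) / (prior.f0 + params.alpha.sum()))


def sample_beta(
    counts: CountMatrix,
    volumes: np.ndarray,
    params: ModelParams,
    prior: PriorConfig,
    rng: np.random.Generator,
    aug: AugmentedState | None = None,
) -> None:
    """Polya-Gamma-augmented Normal update for φ_gt = −log β_gt."""
    nu = np.asarray(volumes, dtype=float)
    m, n = counts.X.shape
    k = params.k
    alpha_cell = params.alpha[:, params.z]
    phi_cell = params.phi[:, params.z]
    lognu = np.log(nu)
    omega = sample_polya_gamma(counts.X + alpha_cell, lognu[None, :] + phi_cell, rng)
    if aug is not None:
        aug.omega = omega
    onehot = np.zeros((n, k))
    onehot[np.arange(n), params.z] = 1.0
    S_omega = omega @ onehot  # (m, k)
    kappa = (counts.X - alpha_cell) / 2.0 - omega * lognu[None, :]
    S_kappa = kappa @ onehot
    var = 1.0 / (prior.gamma + S_omega)
    mean = var * S_kappa
    params.phi = mean + np.sqrt(var) * rng.standard_normal((m, k))


def sample_volume_params(
    volumes: np.ndarray,
    params: ModelParams,
    prior: PriorConfig,
    rng: np.random.Generator,
) -> None:
    """Conjugate Normal–Gamma update of the per-component LogNormal volume
    model, then the Dirichlet-multinomial update of the weights π."""
    v = np.log(np.asarray(volumes, dtype=float))
    k = params.k
    for t in range(k):
        mem = v[params.z == t]
        nt = len(mem)
        prec = params.prec_vol[t]
        post_prec = prior.sigma0 + nt * prec
        post_mean = (prior.sigma0 * prior.mu0 + prec * mem.sum()) / post_prec
        params.mu_vol[t] = rng.normal(post_mean, 1.0 / np.sqrt(post_prec))
        ssq = float(((mem - params.mu_vol[t]) ** 2).sum())
        params.prec_vol[t] = rng.gamma(prior.alpha0 + nt / 2.0) / (prior.beta0 + ssq / 2.0)
    if prior.resample_pi:
        occ = np.bincount(params.z, minlength=k)
        params.pi = rng.dirichlet(prior.dirichlet_conc + occ)


def initial_components(counts: CountMatrix, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seed component labels by k-means on censored log-proportions.

    A uniform random start can merge well-separated components into one
    mode the collapsed Gibbs chain is slow to leave; clustering the
    normalized expression first makes mixing a refinement problem.
    Falls back to random labels for degenerate inputs.
    """
    from scipy.cluster.vq import kmeans2

    X = counts.X.T.astype(float)  # cells × genes
    totals = X.sum(axis=1)
    pos = totals > 0
    z = rng.integers(0, k, size=counts.n)
    if k <= 1 or pos.sum() <= k:
        return z
    logp = np.log(np.maximum(X[pos] / totals[pos, None], 1e-4))
    try:
        _, labels = kmeans2(logp, k, minit="++", seed=int(rng.integers(2**31)))
    except Exception:
        return z
    z[pos] = labels
    return z.astype(np.int64)


def gibbs_sweep(
    counts: CountMatrix,
    volumes: np.ndarray,
    params: ModelParams,
    prior: PriorConfig,
    total_volume: float,
    rng: np.random.Generator,
    aug: AugmentedState | None = None,
    update_z: bool = True,
) -> None:
    """One full parameter sweep with cell boundaries held fixed.

    ``update_z=False`` holds the component labels fixed — used while
    warming up α, β after initialization, so that the first z draw is
    informed rather than uniform.
    """
    if update_z:
        sample_component_assignments(counts, volumes, params, rng)
    sample_rates(counts, volumes, params, prior, total_volume, rng)
    sample_alpha_and_h(counts, volumes, params, prior, rng, aug)
    sample_beta(counts, volumes, params, prior, rng, aug)
    sample_volume_params(volumes, params, prior, rng)


def fit_expression(
    counts: CountMatrix,
    volumes: np.ndarray,
    prior: PriorConfig,
    total_volume: float | None = None,
    n_sweeps: int = 400,
    burnin: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """Run the Gibbs chain on fixed boundaries and return posterior means.

    Used for parameter-recovery checks and as a standalone expression
    fitter; returns posterior-mean ``tau``, ``alpha``, ``beta``, ``pi``,
    the modal component labels and the last parameter state.
    """
    rng = np.random.default_rng() if rng is None else rng
    nu = np.asarray(volumes, dtype=float)
    if total_volume is None:
        total_volume = float(nu.sum())
    params = ModelParams.initial(counts.m, counts.n, prior, rng)
    params.z = initial_components(counts, prior.k, rng)
    sample_rates(counts, nu, params, prior, total_volume, rng)
    for _ in range(20):  # adapt α, β to the initial partition first
        gibbs_sweep(counts, nu, params, prior, total_volume, rng, update_z=False)
    acc = {
        "tau": np.zeros_like(params.tau),
        "alpha": np.zeros_like(params.alpha),
        "beta": np.zeros_like(params.phi),
        "pi": np.zeros_like(params.pi),
    }
    z_votes = np.zeros((prior.k, counts.n), dtype=np.int64)
    kept = 0
    for s in range(n_sweeps):
        gibbs_sweep(counts, nu, params, prior, total_volume, rng)
        if s >= burnin:
            kept += 1
            acc["tau"] += params.tau
            acc["alpha"] += params.alpha
            acc["beta"] += params.beta
            acc["pi"] += params.pi
            z_votes[params.z, np.arange(counts.n)] += 1
    for key in acc:
        acc[key] /= max(kept, 1)
    acc["z_mode"] = np.argmax(z_votes, axis=0)
    acc["params"] = params
    return acc
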