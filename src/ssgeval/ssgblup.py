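"""Single-step animal model: Gibbs sampler, MME solver, reliabilities.

The animal model is ``y = Xb + Za + e`` with ``a ~ N(0, H sigma2_a)`` and
``e ~ N(0, I sigma2_e)``; X carries the intercept and age-class effects.
Sampling works in the Cholesky-transformed equivalent model

    y = Xb + Fa ca + e,   Fa = Z L,   a = L ca,   ca ~ N(0, I sigma2_a)

where ``L L' = H``, so the random effects are a priori independent and the
full conditional of ``ca`` is Gaussian with a diagonal-plus-low-rank
precision that a one-off SVD of ``Fa`` turns into O(q^2) work per sweep.

Variance components get scaled-inverse-chi-square priors (weakly
informative, df 5, scale from an even split of the phenotypic variance);
breeding values, their prediction error variances (posterior variances of
``a``) and reliabilities ``r^2 = 1 - PEV / sigma2_a`` come from the stored
back-transformed samples.  :func:`solve_mme` provides the deterministic
Henderson mixed-model-equations cross-check and the classical
pedigree-BLUP comparator (``K = A``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Pedigree, PhenotypeTable
from .relationship_matrices import RelationshipMatrix

logger = logging.getLogger("ssgeval.ssgblup")


@dataclass
class GibbsPriors:
    """Scaled-inverse-chi-square priors for both variance components."""

    df_a: float = 5.0
    df_e: float = 5.0
    scale_a: float | None = None  # None: var(y)/2 at fit time
    scale_e: float | None = None


@dataclass
class DesignMatrices:
    """Design of the transformed single-step model for one phenotype vector."""

    y: np.ndarray
    X: np.ndarray
    x_labels: list[str]
    Z: np.ndarray  # records x pedigree animals (0/1 incidence)
    Fa: np.ndarray  # Z @ L
    L: np.ndarray  # Cholesky factor of H over the whole pedigree
    animal_ids: list[str]
    record_animal_index: np.ndarray

    def __post_init__(self):
        m = len(self.y)
        for name, M in (("X", self.X), ("Z", self.Z), ("Fa", self.Fa)):
            if M.shape[0] != m:
                raise ValueError(f"{name} has {M.shape[0]} rows, y has {m}")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient after the reference-class drop")


@dataclass
class ModelFit:
    """Posterior summaries (or MME solutions) of the animal model."""

    animal_ids: list[str]
    b: np.ndarray
    b_labels: list[str]
    gebv: np.ndarray  # posterior mean breeding values, cm
    pev: np.ndarray  # posterior variance of breeding values, cm^2
    sigma2_a: float
    sigma2_e: float
    b_sd: np.ndarray | None = None
    sigma2_a_sd: float | None = None
    sigma2_e_sd: float | None = None
    h2_sd: float | None = None
    n_iter: int = 0
    burn_in: int = 0
    thin: int = 1
    ess: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)

    @property
    def reliability(self) -> np.ndarray:
        return reliabilities(self)


def build_design(
    phenos: PhenotypeTable, ped: Pedigree, Hchol: RelationshipMatrix
) -> DesignMatrices:
    """Incidence matrices for intercept + age classes and the animal effect.

    Age class 1 is the reference level; classes absent from the data lose
    their column (warning).  Records are sorted into pedigree order.
    """
    if len(phenos) == 0:
        raise ValueError("empty phenotype set")
    if Hchol.index != list(ped.ids):
        raise ValueError("Cholesky factor index must cover the pedigree")
    df = phenos.data
    ped_pos = ped.indices_of(df["animal_id"].tolist())
    order = np.argsort(ped_pos, kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    rec_idx = ped_pos[order]

    y = df["height"].to_numpy(dtype=np.float64)
    cls = df["age_class"].to_numpy()
    present = [k for k in (1, 2, 3, 4, 5) if (cls == k).any()]
    for k in (1, 2, 3, 4, 5):
        if k not in present:
            logger.warning("age class %d absent from data; column dropped", k)
    cols = [np.ones(len(y))]
    labels = ["intercept"]
    # the first present class is the reference level
    for k in present[1:]:
        cols.append((cls == k).astype(np.float64))
        labels.append(f"age_class_{k}")
    X = np.column_stack(cols)

    q = len(ped)
    Z = np.zeros((len(y), q))
    Z[np.arange(len(y)), rec_idx] = 1.0
    L = Hchol.values
    Fa = L[rec_idx, :]
    return DesignMatrices(
        y=y,
        X=X,
        x_labels=labels,
        Z=Z,
        Fa=Fa,
        L=L,
        animal_ids=list(ped.ids),
        record_animal_index=rec_idx,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _ess(chain: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        acf = np.correlate(x, x, mode="full")[n - 1 :] / (
            np.arange(n, 0, -1) * x.var()
        )
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k]
        if pair < 0:
            break
        s += pair
    return float(n / max(1.0, 1.0 + 2.0 * s))


def fit_gibbs(
    design: DesignMatrices,
    n_iter: int = 30_000,
    burn_in: int = 5_000,
    thin: int = 5,
    seed: int = 0,
    priors: GibbsPriors | None = None,
    fixed_variances: tuple[float, float] | None = None,
    rao_blackwell: bool = False,
) -> ModelFit:
    """Collapsed Gibbs sampler for the transformed single-step model.

    The fixed effects are integrated out by projecting the model onto the
    orthogonal complement of ``col(X)`` (the REML transformation), and a
    one-off SVD of the projected design splits the independent random
    effects ``ca`` into data-informed coordinates ``w`` (rank r) and a
    prior-only complement.  The chain state is just ``(w, sigma2_a,
    sigma2_e)`` with exact Gaussian / scaled-inverse-chi-square
    conditionals and O(r) work per sweep; the prior-only coordinates and
    the fixed effects are redrawn from their conditionals only when a
    sample is stored.  Collapsing removes the two classic slow modes of
    animal-model samplers — the intercept vs. mean-breeding-value
    random walk and the null-space feedback on the genetic variance —
    without changing the posterior.

    ``fixed_variances=(sigma2_a, sigma2_e)`` freezes the variances (the
    degenerate-prior mode used to cross-check the MME solver).  With
    ``rao_blackwell=True`` the reported posterior means of ``b`` and the
    breeding values average the analytic conditional means instead of
    the draws, removing almost all Monte-Carlo noise from the point
    estimates (prediction error variances still come from the sampled
    draws).  Deterministic given ``seed``.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    priors = priors or GibbsPriors()
    rng = np.random.default_rng(seed)
    y, X, F, L = design.y, design.X, design.Fa, design.L
    m, q = F.shape
    p = X.shape[1]
    if m <= p:
        raise ValueError("need more records than fixed-effect levels")

    vy = float(np.var(y)) if np.var(y) > 0 else 1.0
    Sa = priors.scale_a if priors.scale_a is not None else vy / 2
    Se = priors.scale_e if priors.scale_e is not None else vy / 2

    # one-off decompositions: REML projection, then SVD of the projected
    # design  K'F = U diag(s) V'  with K an orthonormal basis of col(X)^perp
    Qfull, _ = np.linalg.qr(X, mode="complete")
    K = Qfull[:, p:]  # m x (m-p)
    Fs = K.T @ F
    ys = K.T @ y
    U, s, Vt = np.linalg.svd(Fs, full_matrices=False)
    V = Vt.T  # q x r
    r_rank = len(s)
    uy = U.T @ ys  # constant across sweeps
    yperp2 = float(ys @ ys - uy @ uy)  # ||ys||^2 outside span(U)
    XtX = X.T @ X
    XtX_chol = np.linalg.cholesky(XtX)

    if fixed_variances is not None:
        s2a, s2e = map(float, fixed_variances)
    else:
        s2a, s2e = vy / 2, vy / 2
    w = np.zeros(r_rank)

    a_mean = np.zeros(q)
    a_m2 = np.zeros(q)
    b_sum = np.zeros(p)
    b_sum2 = np.zeros(p)
    rb_a_sum = np.zeros(q)
    rb_b_sum = np.zeros(p)
    chains = {"sigma2_a": [], "sigma2_e": [], "h2": []}
    stored = 0

    for it in range(n_iter):
        lam = s2e / s2a
        denom = s**2 + lam
        # --- informed coordinates w | variances (b collapsed) ---
        mean_w = (s / denom) * uy
        w = mean_w + np.sqrt(s2e) * rng.standard_normal(r_rank) / np.sqrt(denom)
        # --- variances (b and prior-only coordinates collapsed) ---
        if fixed_variances is None:
            ess_resid = yperp2 + float(np.sum((uy - s * w) ** 2))
            s2a = (priors.df_a * Sa + w @ w) / rng.chisquare(
                priors.df_a + r_rank
            )
            s2e = (priors.df_e * Se + ess_resid) / rng.chisquare(
                priors.df_e + m - p
            )
            if not (np.isfinite(s2a) and np.isfinite(s2e)) or s2a <= 0 or s2e <= 0:
                raise FloatingPointError(
                    f"divergent variance draw at iteration {it}"
                )
        if it >= burn_in and (it - burn_in) % thin == 0:
            stored += 1
            # redraw the prior-only complement of ca and the fixed effects
            if q > r_rank:
                z2 = rng.standard_normal(q)
                ca = V @ w + np.sqrt(s2a) * (z2 - V @ (Vt @ z2))
            else:
                ca = V @ w
            bhat = np.linalg.solve(XtX, X.T @ (y - F @ ca))
            zb = rng.standard_normal(p)
            b = bhat + np.sqrt(s2e) * np.linalg.solve(XtX_chol.T, zb)
            a = L @ ca
            delta = a - a_mean
            a_mean += delta / stored
            a_m2 += delta * (a - a_mean)
            b_sum += b
            b_sum2 += b * b
            if rao_blackwell:
                a_cond = L @ (V @ mean_w)
                rb_a_sum += a_cond
                rb_b_sum += np.linalg.solve(
                    XtX, X.T @ (y - F @ (V @ mean_w))
                )
            chains["sigma2_a"].append(s2a)
            chains["sigma2_e"].append(s2e)
            chains["h2"].append(s2a / (s2a + s2e))

    if stored < 2:
        raise ValueError("chain too short to summarise")
    pev = a_m2 / (stored - 1)
    s2a_chain = np.array(chains["sigma2_a"])
    s2e_chain = np.array(chains["sigma2_e"])
    h2_chain = np.array(chains["h2"])
    b_mean = b_sum / stored
    b_var = np.maximum(b_sum2 / stored - b_mean**2, 0.0)
    return ModelFit(
        animal_ids=list(design.animal_ids),
        b=rb_b_sum / stored if rao_blackwell else b_mean,
        b_labels=list(design.x_labels),
        gebv=rb_a_sum / stored if rao_blackwell else a_mean,
        pev=pev,
        sigma2_a=float(s2a_chain.mean()),
        sigma2_e=float(s2e_chain.mean()),
        b_sd=np.sqrt(b_var),
        sigma2_a_sd=float(s2a_chain.std(ddof=1)),
        sigma2_e_sd=float(s2e_chain.std(ddof=1)),
        h2_sd=float(h2_chain.std(ddof=1)),
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        ess={k: _ess(np.array(v)) for k, v in chains.items()},
    )


# ---------------------------------------------------------------------------
# Deterministic mixed-model equations
# ---------------------------------------------------------------------------


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    Kinv: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
):
    """Henderson's MME at fixed variance components.

    Solves ``[X'X X'Z; Z'X Z'Z + Kinv*lambda] [b; a] = [X'y; Z'y]`` with
    ``lambda = sigma2_e / sigma2_a`` and K the chosen relationship matrix
    (H for single-step, A for classical pedigree BLUP).  PEV is the
    a-block diagonal of the inverted coefficient matrix times sigma2_e.
    """
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    lam = sigma2_e / sigma2_a
    p, q = X.shape[1], Z.shape[1]
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z + Kinv * lam
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular mixed-model equations: fixed effects confounded with "
            "the animal effect (check X for collinear columns)"
        ) from e
    sol = Cinv @ rhs
    b, a = sol[:p], sol[p:]
    pev = sigma2_e * np.diag(Cinv)[p:]
    return b, a, pev


def solve_mme_fit(
    design: DesignMatrices,
    Kinv: RelationshipMatrix,
    sigma2_a: float,
    sigma2_e: float,
) -> ModelFit:
    """MME solve packaged as a :class:`ModelFit` (for comparators/reports)."""
    b, a, pev = solve_mme(
        design.y, design.X, design.Z, Kinv.values, sigma2_a, sigma2_e
    )
    return ModelFit(
        animal_ids=list(design.animal_ids),
        b=b,
        b_labels=list(design.x_labels),
        gebv=a,
        pev=pev,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
    )


def reliabilities(fit: ModelFit) -> np.ndarray:
    """``r^2 = 1 - PEV / sigma2_a`` per animal, clipped to [0, 1]."""
    if fit.sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    raw = 1.0 - fit.pev / fit.sigma2_a
    n_clip = int(((raw < 0) | (raw > 1)).sum())
    if n_clip:
        logger.info("clipped %d reliability value(s) into [0, 1]", n_clip)
    return np.clip(raw, 0.0, 1.0)
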