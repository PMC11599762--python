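"""Partial least squares correlation (PLSC) between connectivity and cognition.

PLSC finds paired linear combinations of brain features ``X`` (subjects x F)
and cognitive scores ``Y`` (subjects x Q) with maximal covariance: after
column standardization, the cross-covariance ``R = Y' X / (S - 1)`` is
decomposed as ``R = U S V'``; columns of ``V`` are brain saliences, columns of
``U`` cognitive saliences and the squared singular values give each
component's share of the total brain-behavior covariance.

Inference follows the standard resampling recipe: component significance by
permuting subject rows of ``Y`` (p < .05), salience reliability by bootstrap
standard scores (|z| > 2), and a robustness loop that repeats the analysis on
random subject subsamples, recording the covariance explained by the
significant components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSignalError, DimensionError

__all__ = [
    "CognitiveScoreTable",
    "PLSCResult",
    "subdomain_scores",
    "plsc",
    "permutation_significance",
    "bootstrap_salience",
    "covariance_explained",
    "robustness_loop",
]


@dataclass
class CognitiveScoreTable:
    """Subject x subdomain score matrix (one aggregated score per subdomain)."""

    values: np.ndarray
    subdomains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("score table must be 2-D (subjects x subdomains)")
        if not self.subdomains:
            self.subdomains = [f"score_{i + 1}" for i in range(self.values.shape[1])]
        if len(self.subdomains) != self.values.shape[1]:
            raise DimensionError("subdomain names do not match columns")
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("non-finite scores")


@dataclass
class PLSCResult:
    """SVD of the brain-behavior cross-covariance plus resampling statistics."""

    singular_values: np.ndarray       # (K,) non-increasing
    brain_saliences: np.ndarray       # (F, K) unit columns
    cognitive_saliences: np.ndarray   # (Q, K) unit columns
    brain_scores: np.ndarray          # (S, K) latent scores X_z @ V
    cognitive_scores: np.ndarray      # (S, K) latent scores Y_z @ U
    p_values: np.ndarray | None = None
    brain_z: np.ndarray | None = None       # bootstrap standard scores
    cognitive_z: np.ndarray | None = None

    @property
    def covariance_shares(self) -> np.ndarray:
        s2 = self.singular_values ** 2
        return s2 / s2.sum()


def _zscore_cols(m: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    sd = m.std(axis=0, ddof=1)
    # relative tolerance: a constant column can leave rounding residue in sd
    scale = np.maximum(np.abs(m).max(axis=0), 1.0)
    flat = np.flatnonzero(sd <= 1e-12 * scale)
    if flat.size:
        raise DegenerateSignalError(f"constant {what} column {int(flat[0])}")
    return (m - m.mean(axis=0)) / sd


def subdomain_scores(raw: pd.DataFrame,
                     mapping: dict[str, list[str]]) -> CognitiveScoreTable:
    """Aggregate raw instrument scores into one score per cognitive subdomain.

    Subdomains with a single raw score pass through z-scored; subdomains with
    several raw scores are summarized by the first principal component of their
    z-scored columns, sign-aligned so the mean loading is positive, and
    re-standardized.
    """
    cols = []
    names = []
    for sub, raw_cols in mapping.items():
        if not raw_cols:
            raise DimensionError(f"subdomain {sub!r} has no raw scores")
        missing = [c for c in raw_cols if c not in raw.columns]
        if missing:
            raise DimensionError(f"raw column(s) {missing} not in table")
        block = _zscore_cols(raw[raw_cols].to_numpy(), f"raw score ({sub})")
        if block.shape[1] == 1:
            score = block[:, 0]
        else:
            u, s, vt = np.linalg.svd(block, full_matrices=False)
            load = vt[0]
            if load.mean() < 0:
                load = -load
            score = block @ load
            score = (score - score.mean()) / score.std(ddof=1)
        cols.append(score)
        names.append(sub)
    return CognitiveScoreTable(np.column_stack(cols), names)


def plsc(x: np.ndarray, y) -> PLSCResult:
    """Singular value decomposition of the standardized cross-covariance.

    Parameters
    ----------
    x : (S, F) brain feature matrix.
    y : (S, Q) score matrix or :class:`CognitiveScoreTable`.
    """
    yv = y.values if isinstance(y, CognitiveScoreTable) else np.asarray(y)
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != yv.shape[0]:
        raise DimensionError("X and Y have different numbers of subjects")
    if x.shape[0] < 3:
        raise DimensionError("need at least 3 subjects")
    xz = _zscore_cols(x, "brain feature")
    yz = _zscore_cols(yv, "cognitive score")
    r = yz.T @ xz / (x.shape[0] - 1)
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    v = vt.T
    return PLSCResult(
        singular_values=s,
        brain_saliences=v,
        cognitive_saliences=u,
        brain_scores=xz @ v,
        cognitive_scores=yz @ u,
    )


def _null_singulars(xz: np.ndarray, yz: np.ndarray, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
    s_subjects = xz.shape[0]
    k = min(yz.shape[1], xz.shape[1])
    out = np.empty((n_perm, k))
    for p in range(n_perm):
        perm = rng.permutation(s_subjects)
        r = yz[perm].T @ xz / (s_subjects - 1)
        out[p] = np.linalg.svd(r, compute_uv=False)
    return out


def permutation_significance(x: np.ndarray, y, n_perm: int = 1000,
                             seed: int = 0, null: str = "max") -> np.ndarray:
    """Permutation p-values for the PLSC components.

    Subject rows of ``Y`` are permuted ``n_perm`` times and each observed
    singular value is compared with the permutation distribution, with the
    +1 small-sample correction in numerator and denominator.

    ``null="max"`` (default) compares every component against the null
    distribution of the *largest* permuted singular value; because the observed
    values are ordered, the chance of declaring any component significant on
    null data is then exactly the nominal level.  ``null="marginal"`` compares
    each sigma_i against the null of its own rank instead, which tests each
    component at nominal level marginally but inflates the family-wise rate.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if null not in ("max", "marginal"):
        raise ValueError("null must be 'max' or 'marginal'")
    yv = y.values if isinstance(y, CognitiveScoreTable) else np.asarray(y)
    xz = _zscore_cols(np.asarray(x, dtype=np.float64), "brain feature")
    yz = _zscore_cols(yv, "cognitive score")
    obs = np.linalg.svd(yz.T @ xz / (x.shape[0] - 1), compute_uv=False)
    rng = np.random.default_rng(seed)
    nulls = _null_singulars(xz, yz, n_perm, rng)
    ref = nulls.max(axis=1, keepdims=True) if null == "max" else nulls
    exceed = (ref >= obs[None, :]).sum(axis=0)
    return (exceed + 1.0) / (n_perm + 1.0)


def _align(sal: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Match bootstrap components to the reference by maximal |correlation|
    (greedy) and align signs."""
    k = ref.shape[1]
    c = np.abs(ref.T @ sal)  # (K, K) |cosine| since columns are unit norm
    order = np.full(k, -1)
    used = set()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(c), c.shape)
        order[i] = j
        used.add(j)
        c[i, :] = -1
        c[:, j] = -1
    out = sal[:, order]
    signs = np.sign(np.sum(ref * out, axis=0))
    signs[signs == 0] = 1.0
    return out * signs, order, signs


def bootstrap_salience(x: np.ndarray, y, n_boot: int = 1000,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap standard scores for brain and cognitive saliences.

    Subjects are resampled with replacement; each bootstrap's saliences are
    matched to the original components (by maximal absolute correlation) and
    sign-aligned before the elementwise standard deviation is taken.  The
    standard score of a salience entry is its original value divided by its
    bootstrap standard deviation.  Degenerate resamples (a constant column)
    are redrawn, up to a capped number of attempts.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap resamples for a standard score")
    yv = y.values if isinstance(y, CognitiveScoreTable) else np.asarray(y)
    base = plsc(x, yv)
    rng = np.random.default_rng(seed)
    s_subjects = x.shape[0]
    brain = np.empty((n_boot,) + base.brain_saliences.shape)
    cog = np.empty((n_boot,) + base.cognitive_saliences.shape)
    attempts_left = 10 * n_boot
    b = 0
    while b < n_boot:
        if attempts_left <= 0:
            raise DegenerateSignalError("too many degenerate bootstrap resamples")
        attempts_left -= 1
        sel = rng.integers(0, s_subjects, size=s_subjects)
        try:
            res = plsc(x[sel], yv[sel])
        except DegenerateSignalError:
            continue
        bs, order, signs = _align(res.brain_saliences, base.brain_saliences)
        brain[b] = bs
        cog[b] = res.cognitive_saliences[:, order] * signs
        b += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        brain_z = base.brain_saliences / brain.std(axis=0, ddof=1)
        cog_z = base.cognitive_saliences / cog.std(axis=0, ddof=1)
    return brain_z, cog_z


def covariance_explained(result: PLSCResult, p_values: np.ndarray | None = None,
                         alpha: float = 0.05) -> float:
    """Share of squared singular values carried by the significant components.

    Returns 0 when no component is significant.
    """
    p = p_values if p_values is not None else result.p_values
    if p is None:
        raise DimensionError("p-values required (run permutation_significance)")
    sig = np.asarray(p) < alpha
    s2 = result.singular_values ** 2
    return float(s2[sig].sum() / s2.sum()) if sig.any() else 0.0


def robustness_loop(x: np.ndarray, y, n_sub: int = 80, n_rep: int = 100,
                    n_perm: int = 200, n_boot: int = 0, alpha: float = 0.05,
                    z_thresh: float = 2.0, reliable_frac: float = 0.6,
                    seed: int = 0, null: str = "max") -> dict:
    """Subsampled PLSC robustness analysis.

    Per repetition a subject subsample of size ``n_sub`` is drawn without
    replacement, PLSC and permutation significance are re-run and the
    covariance explained by significant components recorded.  When
    ``n_boot > 0`` each repetition also computes bootstrap standard scores and
    a brain salience entry is flagged reliable when ``|z| > z_thresh`` in more
    than ``reliable_frac`` of the repetitions.

    Returns a dict with ``covariance_explained`` (ndarray, one per repetition)
    and, when bootstrapped, ``reliable`` (bool ndarray over brain features for
    component 1) and ``reliability_rate``.
    """
    yv = y.values if isinstance(y, CognitiveScoreTable) else np.asarray(y)
    s_subjects = x.shape[0]
    if n_sub > s_subjects:
        raise DimensionError("subsample larger than the cohort")
    rng = np.random.default_rng(seed)
    cov = np.empty(n_rep)
    flags = np.zeros((n_rep, x.shape[1]), dtype=bool) if n_boot else None
    for rep in range(n_rep):
        sel = rng.choice(s_subjects, size=n_sub, replace=False)
        xs, ys = x[sel], yv[sel]
        res = plsc(xs, ys)
        p = permutation_significance(xs, ys, n_perm=n_perm,
                                     seed=int(rng.integers(2**31)), null=null)
        cov[rep] = covariance_explained(res, p, alpha=alpha)
        if n_boot:
            bz, _ = bootstrap_salience(xs, ys, n_boot=n_boot,
                                       seed=int(rng.integers(2**31)))
            flags[rep] = np.abs(bz[:, 0]) > z_thresh
    out = {"covariance_explained": cov}
    if n_boot:
        rate = flags.mean(axis=0)
        out["reliability_rate"] = rate
        out["reliable"] = rate > reliable_frac
    return out
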