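"""Univariate feature filtering: random-variance tests + permutation control.

The random-variance model treats each gene's true variance sigma_g^2 as drawn
from an inverse-gamma prior, equivalently precision 1/sigma_g^2 ~
Gamma(a, scale b).  Given the usual residual variance s_g^2 on nu_g degrees
of freedom (nu s^2 / sigma^2 ~ chi^2_nu), the posterior-shrunken variance

    s~_g^2 = (nu_g s_g^2 + 2/b) / (nu_g + 2a)

replaces s_g^2 in the per-gene F statistic, whose null distribution becomes
F(K-1, nu_g + 2a).  The two-class statistic is the square of the moderated
t.  Under the same model the marginal distribution of s_g^2 satisfies
a * b * s_g^2 ~ F(nu_g, 2a), which is what the prior fit maximizes.

The multivariate permutation filter chooses the largest p-value cutoff
alpha* such that, with the configured confidence over random relabelings,
the number of genes passing alpha* by chance stays at or below the allowed
number of false positives.  It controls the *number* of false positives, not
a rate, which is what makes very stringent settings (10 false positives at
99% confidence) meaningful genome-wide.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .datatypes import ExpressionMatrix, SampleAnnotation
from .errors import IsmlError, ValidationError

__all__ = [
    "VariancePrior",
    "GeneTestResult",
    "SignificantGeneList",
    "ComparisonSpec",
    "fit_variance_prior",
    "residual_variances",
    "random_variance_test",
    "moderated_f_pvalues",
    "multivariate_permutation_filter",
    "run_comparison_suite",
    "standard_suite",
]


@dataclass(frozen=True)
class VariancePrior:
    """Inverse-gamma prior on gene variances: precision ~ Gamma(a, scale b)."""

    a: float
    b: float
    diffuse: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b) and self.a > 0 and self.b > 0):
            raise ValidationError("variance prior parameters must be finite and positive")


#: essentially-uninformative prior: negligible extra df and sum of squares
DIFFUSE_PRIOR = VariancePrior(a=1e-6, b=1e6, diffuse=True)


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    statistic: float
    p_value: float
    class_means: dict[str, float]
    df_num: int
    df_den: float
    testable: bool


@dataclass
class SignificantGeneList:
    """Genes surviving one comparison (or the union of several)."""

    comparison_name: str
    gene_ids: list[str]
    p_values: np.ndarray
    alpha_star: float
    settings: dict
    membership: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# prior estimation
# ---------------------------------------------------------------------------

def residual_variances(
    m: ExpressionMatrix, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-class variances s_g^2 and their df for every testable gene."""
    labels = np.asarray(labels)
    X = m.values
    mask = m.mask & np.isfinite(X) & ~m.spikein[:, None]
    classes = np.unique(labels)
    ssw = np.zeros(m.n_genes)
    ntot = np.zeros(m.n_genes)
    testable = np.ones(m.n_genes, dtype=bool)
    for cls in classes:
        cols = labels == cls
        mk = mask[:, cols]
        xk = np.where(mk, X[:, cols], 0.0)
        nk = mk.sum(axis=1)
        sk = xk.sum(axis=1)
        ssk = (xk**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ssw += np.where(nk > 0, ssk - sk**2 / np.maximum(nk, 1), 0.0)
        ntot += nk
        testable &= nk >= 2
    testable &= ~m.spikein
    df = ntot - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df > 0, ssw / np.maximum(df, 1), np.nan)
    keep = testable & (df >= 1) & np.isfinite(s2)
    return s2[keep], df[keep].astype(int)


def fit_variance_prior(
    variances: Sequence[float], dfs: Sequence[int]
) -> VariancePrior:
    """Maximum-marginal-likelihood fit of the inverse-gamma variance prior.

    Under the model, a*b*s_g^2 ~ F(nu_g, 2a); the fit maximizes the product
    of these marginal densities over (a, b) on the log scale.  Requires at
    least 10 genes; a degenerate input (no spread in the variances) falls
    back to the diffuse prior with a warning.
    """
    s2 = np.asarray(variances, dtype=float)
    nu = np.asarray(dfs, dtype=float)
    if s2.shape != nu.shape:
        raise ValidationError("variances and dfs must align")
    ok = np.isfinite(s2) & (s2 > 0) & (nu >= 1)
    s2, nu = s2[ok], nu[ok]
    if len(s2) < 10:
        raise ValidationError("need at least 10 genes with df >= 1 to fit the prior")
    log_s2 = np.log(s2)
    if np.ptp(log_s2) < 1e-12:
        warnings.warn(
            "all residual variances identical; falling back to a diffuse prior",
            stacklevel=2,
        )
        return DIFFUSE_PRIOR

    def negloglik(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        # density of s^2 when a*b*s^2 ~ F(nu, 2a)
        ll = stats.f.logpdf(a * b * s2, nu, 2 * a) + math.log(a * b)
        return -float(np.sum(ll))

    # moment-based start: E[s^2] ~ 1/(b(a-1)) for a>1; spread sets a
    a0 = 3.0
    b0 = 1.0 / (max(np.mean(s2), 1e-12) * (a0 - 1))
    res = optimize.minimize(
        negloglik, x0=np.log([a0, b0]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    a, b = np.exp(res.x)
    if not res.success or not np.isfinite(a * b) or a > 1e6:
        warnings.warn("variance-prior fit did not converge; using diffuse prior", stacklevel=2)
        return DIFFUSE_PRIOR
    return VariancePrior(a=float(a), b=float(b))


# ---------------------------------------------------------------------------
# moderated F across genes (and batches of label permutations)
# ---------------------------------------------------------------------------

def _onehot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (labels[:, None] == classes[None, :]).astype(float)


def moderated_f_pvalues(
    values: np.ndarray,
    mask: np.ndarray,
    label_matrix: np.ndarray,
    prior: VariancePrior,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized moderated F over genes x label assignments.

    ``label_matrix`` has shape (n_samples, K, R): R one-hot class
    assignments (R=1 for the observed labels).  Returns (F, p, df_den), each
    of shape (n_genes, R); entries where any class has fewer than 2 usable
    values are untestable and reported as F=nan, p=1.
    """
    G, N = values.shape
    _, K, R = label_matrix.shape
    Xm = np.where(mask, values, 0.0)
    X2m = np.where(mask, values**2, 0.0)
    M = mask.astype(float)
    Y = label_matrix.reshape(N, K * R)
    n = (M @ Y).reshape(G, K, R)
    s = (Xm @ Y).reshape(G, K, R)
    ss = (X2m @ Y).reshape(G, K, R)

    testable = (n >= 2).all(axis=1)
    n_safe = np.maximum(n, 1.0)
    ntot = n.sum(axis=1)
    stot = s.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssw = (ss - s**2 / n_safe).sum(axis=1)
        ssb = (s**2 / n_safe).sum(axis=1) - stot**2 / np.maximum(ntot, 1.0)
    nu = ntot - K
    df_den = nu + 2 * prior.a
    shrunk = (ssw + 2.0 / prior.b) / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (K - 1)) / shrunk
    F = np.where(testable & np.isfinite(F), F, np.nan)
    F = np.where(testable & ~np.isfinite(F) & (ssb == 0), 0.0, F)
    p = np.ones_like(F)
    good = np.isfinite(F)
    p[good] = stats.f.sf(np.maximum(F[good], 0.0), K - 1, df_den[good])
    # numerically negative SSB from cancellation -> statistic 0, p 1
    F = np.where(good & (F < 0), 0.0, F)
    p = np.where(good & np.isclose(F, 0.0), 1.0, p)
    return F, p, df_den


def random_variance_test(
    m: ExpressionMatrix,
    labels: Sequence[str],
    prior: VariancePrior | None = None,
) -> list[GeneTestResult]:
    """Per-gene moderated F-test (squared moderated t when K = 2).

    ``prior`` defaults to a fit on this matrix's own residual variances.
    Genes with fewer than 2 usable values in any class are returned with
    ``testable=False`` and p = 1 rather than raising.
    """
    labels = np.asarray(labels)
    if len(labels) != m.n_samples:
        raise ValidationError("labels must align with samples")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    if prior is None:
        prior = fit_variance_prior(*residual_variances(m, labels))
    mask = m.mask & np.isfinite(m.values)
    Y = _onehot(labels, classes)[:, :, None]
    F, p, df_den = moderated_f_pvalues(m.values, mask, Y, prior)

    results: list[GeneTestResult] = []
    Xm = np.where(mask, m.values, 0.0)
    for gi, gene in enumerate(m.gene_ids):
        means = {}
        for ki, cls in enumerate(classes):
            cols = labels == cls
            nk = mask[gi, cols].sum()
            means[str(cls)] = float(Xm[gi, cols].sum() / nk) if nk else float("nan")
        testable = np.isfinite(F[gi, 0])
        results.append(
            GeneTestResult(
                gene_id=gene,
                statistic=float(F[gi, 0]) if testable else float("nan"),
                p_value=float(p[gi, 0]),
                class_means=means,
                df_num=len(classes) - 1,
                df_den=float(df_den[gi, 0]),
                testable=bool(testable),
            )
        )
    return results


# ---------------------------------------------------------------------------
# multivariate permutation filter
# ---------------------------------------------------------------------------

def _n_distinct_assignments(counts: Sequence[int]) -> float:
    total = sum(counts)
    log_n = special.gammaln(total + 1) - sum(special.gammaln(c + 1) for c in counts)
    return float(np.exp(min(log_n, 700)))


def _enumerate_assignments(labels: np.ndarray) -> np.ndarray:
    """All distinct arrangements of a label multiset (rows)."""
    classes, counts = np.unique(labels, return_counts=True)
    out = []
    seen: set[tuple] = set()
    for perm in itertools.permutations(labels.tolist()):
        if perm not in seen:
            seen.add(perm)
            out.append(perm)
    return np.array(out)


def multivariate_permutation_filter(
    m: ExpressionMatrix,
    labels: Sequence[str],
    n_permutations: int = 1000,
    confidence: float = 0.99,
    max_false_positives: int = 10,
    prior: VariancePrior | None = None,
    seed: int | np.random.Generator = 0,
    comparison_name: str = "comparison",
    enumeration_limit: int = 20_000,
    _perm_chunk: int = 64,
) -> SignificantGeneList:
    """Select genes with the number of false positives controlled by permutation.

    Chooses the largest p-value cutoff alpha* (searched over the observed
    p-values) such that the ``confidence``-quantile of the count of genes
    reaching alpha* under random label permutations is at most
    ``max_false_positives``, then returns the genes whose observed p <=
    alpha*, ordered by ascending p.  When the number of distinct label
    arrangements is below both ``n_permutations`` and ``enumeration_limit``
    the full permutation space is enumerated instead of sampled.

    The variance prior is fitted once on the observed labelling and reused
    across permutations (its inputs — pooled residual variances — are only
    weakly label-dependent, and a fixed prior keeps the permutation null
    exchangeable).
    """
    if not 0 < confidence < 1:
        raise IsmlError("confidence must lie in (0, 1)")
    if n_permutations < 1:
        raise IsmlError("n_permutations must be >= 1")
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    regular = ~m.spikein
    sub = m.subset_genes(regular)
    mask = sub.mask & np.isfinite(sub.values)
    classes = np.unique(labels)
    if prior is None:
        prior = fit_variance_prior(*residual_variances(sub, labels))

    Y_obs = _onehot(labels, classes)[:, :, None]
    F_obs, p_obs, _ = moderated_f_pvalues(sub.values, mask, Y_obs, prior)
    F_obs, p_obs = F_obs[:, 0], p_obs[:, 0]
    keep = np.isfinite(F_obs)  # testable under the observed labelling
    gene_ids = [g for g, k in zip(sub.gene_ids, keep) if k]
    p_obs = p_obs[keep]

    # permutation p-values (rows: kept genes, cols: permutations)
    counts = np.unique(labels, return_counts=True)[1]
    n_distinct = _n_distinct_assignments(counts)
    if n_distinct <= min(n_permutations, enumeration_limit):
        perms = _enumerate_assignments(labels)
    else:
        perms = np.stack([rng.permutation(labels) for _ in range(n_permutations)])
    R = len(perms)
    p_perm = np.empty((len(gene_ids), R), dtype=np.float32)
    vals = sub.values[keep]
    msk = mask[keep]
    for start in range(0, R, _perm_chunk):
        chunk = perms[start : start + _perm_chunk]
        Y = np.stack([_onehot(c, classes) for c in chunk], axis=2)
        _, p_chunk, _ = moderated_f_pvalues(vals, msk, Y, prior)
        p_perm[:, start : start + len(chunk)] = p_chunk

    p_perm_sorted = np.sort(p_perm, axis=0)

    def fp_quantile(alpha: float) -> float:
        # per permutation, #genes with p <= alpha; conservative upper quantile
        cnt = np.sum(p_perm_sorted <= alpha, axis=0)
        return float(np.quantile(cnt, confidence, method="higher"))

    candidates = np.sort(np.unique(p_obs))
    lo, hi = -1, len(candidates) - 1  # find largest index with quantile <= max_fp
    best = -1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if fp_quantile(float(candidates[mid])) <= max_false_positives:
            lo = mid
            best = mid
        else:
            hi = mid - 1
    if best >= 0 and fp_quantile(float(candidates[best])) > max_false_positives:
        best = -1
    alpha_star = float(candidates[best]) if best >= 0 else 0.0

    order = np.argsort(p_obs, kind="stable")
    selected = [
        (gene_ids[i], float(p_obs[i])) for i in order if p_obs[i] <= alpha_star
    ] if alpha_star > 0 else []
    return SignificantGeneList(
        comparison_name=comparison_name,
        gene_ids=[g for g, _ in selected],
        p_values=np.array([p for _, p in selected]),
        alpha_star=alpha_star,
        settings={
            "n_permutations": R,
            "confidence": confidence,
            "max_false_positives": max_false_positives,
            "enumerated": bool(n_distinct <= min(n_permutations, enumeration_limit)),
            "prior_a": prior.a,
            "prior_b": prior.b,
        },
    )


# ---------------------------------------------------------------------------
# comparison suites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonSpec:
    """One class-comparison analysis: a sample subset and a label partition."""

    name: str
    selector: Callable[[SampleAnnotation], bool]
    label_of: Callable[[SampleAnnotation], str]


def standard_suite(
    annotations: Sequence[SampleAnnotation],
    control_label: str = "control",
) -> list[ComparisonSpec]:
    """The pooled-2-class plus per-block concentration-series suite.

    For each treatment compound: one 2-class comparison of pooled controls
    vs all samples of that compound (the other compound's samples excluded),
    and, for each experiment block containing the compound, one multi-class
    comparison across that block's concentration groups with the block's
    controls included.  With two compounds and three blocks this is the
    classic eight-analysis layout.
    """
    compounds = sorted({a.compound for a in annotations if a.compound})
    blocks = sorted({a.experiment_block for a in annotations if a.experiment_block})
    suite: list[ComparisonSpec] = []
    for compound in compounds:
        suite.append(
            ComparisonSpec(
                name=f"{compound}-{control_label}",
                selector=lambda a, c=compound: a.compound == c
                or a.class_label == control_label,
                label_of=lambda a, c=compound: c
                if a.compound == c
                else control_label,
            )
        )
        for block in blocks:
            members = [
                a
                for a in annotations
                if a.experiment_block == block
                and (a.compound == compound or a.class_label == control_label)
            ]
            if not any(a.compound == compound for a in members):
                continue
            suite.append(
                ComparisonSpec(
                    name=f"{compound}-{block}",
                    selector=lambda a, c=compound, bl=block: a.experiment_block == bl
                    and (a.compound == c or a.class_label == control_label),
                    label_of=lambda a, c=compound: f"conc{a.concentration:g}"
                    if a.compound == c
                    else control_label,
                )
            )
    return suite


def run_comparison_suite(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    suite: Sequence[ComparisonSpec],
    n_permutations: int = 1000,
    confidence: float = 0.99,
    max_false_positives: int = 10,
    seed: int = 0,
) -> tuple[SignificantGeneList, list[SignificantGeneList]]:
    """Run every comparison, returning the de-duplicated union and each list.

    Permutations are drawn within each comparison's sample subset only.  A
    comparison whose partition leaves a class empty (or has fewer than 2
    classes) is skipped with a warning and recorded in the union's settings.
    The union's genes are ordered by their best (smallest) p-value across
    comparisons; membership records which comparisons selected each gene.
    """
    ann_by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in m.sample_ids if s not in ann_by_id]
    if missing:
        raise ValidationError(f"samples without annotation: {missing[:3]}")
    rng = np.random.default_rng(seed)
    per_comparison: list[SignificantGeneList] = []
    skipped: list[str] = []
    best_p: dict[str, float] = {}
    membership: dict[str, set[str]] = {}
    for spec in suite:
        sel_ids = [s for s in m.sample_ids if spec.selector(ann_by_id[s])]
        labels = [spec.label_of(ann_by_id[s]) for s in sel_ids]
        uniq, cls_counts = np.unique(labels, return_counts=True)
        if len(uniq) < 2 or (cls_counts < 2).any():
            warnings.warn(f"comparison {spec.name!r} skipped: degenerate classes")
            skipped.append(spec.name)
            continue
        sub = m.subset_samples(sel_ids)
        result = multivariate_permutation_filter(
            sub,
            labels,
            n_permutations=n_permutations,
            confidence=confidence,
            max_false_positives=max_false_positives,
            seed=rng,
            comparison_name=spec.name,
        )
        per_comparison.append(result)
        for g, p in zip(result.gene_ids, result.p_values):
            best_p[g] = min(best_p.get(g, 1.0), float(p))
            membership.setdefault(g, set()).add(spec.name)

    ordered = sorted(best_p, key=lambda g: (best_p[g], g))
    union = SignificantGeneList(
        comparison_name="union",
        gene_ids=ordered,
        p_values=np.array([best_p[g] for g in ordered]),
        alpha_star=float("nan"),
        settings={
            "n_permutations": n_permutations,
            "confidence": confidence,
            "max_false_positives": max_false_positives,
            "skipped_comparisons": skipped,
        },
        membership=membership,
    )
    return union, per_comparison
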