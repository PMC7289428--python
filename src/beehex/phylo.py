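"""Pagel's λ phylogenetic signal for a continuous trait on a dated tree.

Under Brownian motion, a trait vector over the tips of a rooted tree is
multivariate normal with covariance σ²·C, where C[i,j] is the shared
root-to-MRCA path length of tips i and j.  Pagel's λ rescales the
off-diagonal of C: λ = 1 recovers Brownian motion, λ = 0 the star
phylogeny (phylogenetic independence).  λ is estimated by maximizing the
profile log-likelihood (root state by GLS, σ² by ML) over [0, λ_max],
and tested either by a likelihood-ratio test against λ = 0 or by
permuting trait values across tips.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "read_tree",
    "phylo_vcv",
    "lambda_transform",
    "bm_loglik",
    "fit_lambda",
    "lambda_significance",
    "PhyloFit",
]


def _normalize_name(name: str) -> str:
    return name.strip().replace(" ", "_")


def read_tree(path: str, format: str | None = None) -> dendropy.Tree:
    """Read a rooted tree from newick or nexus (TRANSLATE blocks supported).

    The format is inferred from the file when not given.  Branch lengths
    are preserved; polytomies are allowed; duplicate tip labels raise.
    """
    if format is None:
        with open(path) as fh:
            head = fh.read(512).lstrip().lower()
        format = "nexus" if head.startswith("#nexus") else "newick"
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {format!r}")
    try:
        tree = dendropy.Tree.get(path=path, schema=format)
    except Exception as exc:  # malformed file or duplicate taxa
        msg = str(exc)
        if "duplicate" in msg.lower() or "multiple" in msg.lower():
            raise ValueError(f"duplicate tip labels in {path}: {msg}") from exc
        raise ValueError(f"could not parse tree file {path}: {msg}") from exc
    labels = [_normalize_name(leaf.taxon.label) for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = {l for l in labels if labels.count(l) > 1}
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Whitespace-normalized tip labels in tree traversal order."""
    return [_normalize_name(leaf.taxon.label) for leaf in tree.leaf_node_iter()]


def phylo_vcv(tree: dendropy.Tree, taxa: list[str] | None = None) -> np.ndarray:
    """Brownian-motion trait covariance implied by the tree.

    C[i, j] is the root-to-MRCA path length shared by tips i and j;
    C[i, i] is the depth of tip i.  Polytomies are handled natively.
    Rows/columns follow ``taxa`` when given, else tree traversal order.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [_normalize_name(leaf.taxon.label) for leaf in leaves]
    if taxa is None:
        taxa = labels
    missing = set(taxa) - set(labels)
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    index = {lab: i for i, lab in enumerate(taxa) if lab in set(taxa)}

    # Node depths from the root, treating a missing root edge length as 0.
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        if edge < 0:
            raise ValueError("negative branch length")
        depth[node] = (depth[parent] if parent is not None else 0.0) + (
            edge if parent is not None else 0.0
        )

    n = len(taxa)
    cov = np.zeros((n, n))
    for leaf, lab in zip(leaves, labels):
        if lab in index:
            i = index[lab]
            cov[i, i] = depth[leaf]

    # Each internal node contributes its depth as the covariance of every
    # tip pair whose MRCA it is: pairs drawn from distinct child subtrees.
    for node in tree.postorder_internal_node_iter():
        child_tipsets = []
        for child in node.child_nodes():
            tips = [
                index[_normalize_name(l.taxon.label)]
                for l in child.leaf_iter()
                if _normalize_name(l.taxon.label) in index
            ]
            child_tipsets.append(tips)
        d = depth[node]
        for a in range(len(child_tipsets)):
            for b in range(a + 1, len(child_tipsets)):
                for i in child_tipsets[a]:
                    for j in child_tipsets[b]:
                        cov[i, j] = d
                        cov[j, i] = d
    return cov


def lambda_transform(cov: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal of C by λ, leaving tip depths unchanged."""
    if not 0.0 <= lam <= 1.0 + 1e-12:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    out = cov * lam
    np.fill_diagonal(out, np.diag(cov))
    return out


def bm_loglik(trait: np.ndarray, cov: np.ndarray) -> tuple[float, float, float]:
    """ML Gaussian log-likelihood of a trait under covariance σ²·C.

    Returns (loglik, sigma2_hat, root_hat) with the root state estimated
    by GLS, μ̂ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1), and σ̂² = (x−μ̂)ᵀC⁻¹(x−μ̂)/n.
    """
    x = np.asarray(trait, dtype=float)
    n = x.size
    try:
        cho = scipy.linalg.cho_factor(cov, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance") from exc
    ones = np.ones(n)
    ci_x = scipy.linalg.cho_solve(cho, x)
    ci_1 = scipy.linalg.cho_solve(cho, ones)
    root = float(ones @ ci_x / (ones @ ci_1))
    resid = x - root
    quad = float(resid @ scipy.linalg.cho_solve(cho, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    if quad <= 0.0:
        # constant trait: likelihood degenerates, report -inf density limit
        return math.inf, 0.0, root
    sigma2 = quad / n
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return loglik, sigma2, root


@dataclass(frozen=True)
class PhyloFit:
    """A fitted Pagel's λ model."""

    lambda_hat: float
    sigma2_hat: float
    root_state: float
    loglik_at_hat: float
    loglik_at_zero: float
    p_value: float | None
    method: str
    n_tips: int


def _match_trait(
    tree: dendropy.Tree, trait: dict[str, float] | "pd.Series"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align trait values with tree tips, pruning tips without data."""
    values = {_normalize_name(str(k)): float(v) for k, v in dict(trait).items()}
    labels = tip_labels(tree)
    have = [lab for lab in labels if lab in values]
    n_pruned = len(labels) - len(have)
    if n_pruned:
        logger.info("pruning %d tips without trait values", n_pruned)
        tree = tree.clone(depth=1)
        keep = set(have)
        tree.retain_taxa_with_labels(
            [
                leaf.taxon.label
                for leaf in tree.leaf_node_iter()
                if _normalize_name(leaf.taxon.label) in keep
            ]
        )
    cov = phylo_vcv(tree, taxa=have)
    x = np.array([values[lab] for lab in have])
    return x, cov, n_pruned


def fit_lambda(
    trait: dict[str, float] | "pd.Series",
    tree: dendropy.Tree,
    lambda_max: float = 1.0,
    xtol: float = 1e-8,
) -> PhyloFit:
    """Maximum-likelihood Pagel's λ by bounded 1-D profile optimization.

    ``trait`` maps tip names (case-sensitive, whitespace/underscore
    normalized) to values.  λ is searched on [0, lambda_max]; ties in
    the profile likelihood break toward smaller λ.
    """
    x, cov, _ = _match_trait(tree, trait)
    if x.size < 4:
        raise ValueError("need at least 4 tips with trait values")

    def negloglik(lam: float) -> float:
        ll, _, _ = bm_loglik(x, lambda_transform(cov, lam))
        return -ll

    res = scipy.optimize.minimize_scalar(
        negloglik, bounds=(0.0, lambda_max), method="bounded",
        options={"xatol": xtol},
    )
    if not res.success:
        raise RuntimeError(f"lambda optimization failed: {res.message}")
    candidates = [(0.0, negloglik(0.0)), (float(res.x), float(res.fun)),
                  (lambda_max, negloglik(lambda_max))]
    # smallest lambda wins ties (within xtol of the best likelihood)
    best = min(c[1] for c in candidates)
    lam_hat = min(lam for lam, nll in candidates if nll <= best + 1e-10)

    ll_hat, sigma2, root = bm_loglik(x, lambda_transform(cov, lam_hat))
    ll_zero, _, _ = bm_loglik(x, lambda_transform(cov, 0.0))
    return PhyloFit(
        lambda_hat=lam_hat,
        sigma2_hat=sigma2,
        root_state=root,
        loglik_at_hat=ll_hat,
        loglik_at_zero=ll_zero,
        p_value=None,
        method="none",
        n_tips=int(x.size),
    )


def lambda_significance(
    trait: dict[str, float] | "pd.Series",
    tree: dendropy.Tree,
    method: str = "LR",
    n_perm: int = 999,
    seed: int = 0,
    lambda_max: float = 1.0,
) -> PhyloFit:
    """Test λ > 0 by likelihood ratio (default) or tip permutation.

    LR: p = P(χ²₁ ≥ 2·(ℓ(λ̂) − ℓ(0))).  Permutation: the trait vector is
    shuffled over tips n_perm times and the observed likelihood gain is
    compared with the permutation distribution,
    p = (1 + #{gain_perm ≥ gain_obs}) / (n_perm + 1).
    """
    if method not in ("LR", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    fit = fit_lambda(trait, tree, lambda_max=lambda_max)
    gain = fit.loglik_at_hat - fit.loglik_at_zero
    if method == "LR":
        p = float(scipy.stats.chi2.sf(2.0 * max(gain, 0.0), df=1))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be ≥ 1")
        values = {str(k): float(v) for k, v in dict(trait).items()}
        names = list(values)
        vals = np.array([values[k] for k in names])
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(vals)
            pfit = fit_lambda(dict(zip(names, perm)), tree, lambda_max=lambda_max)
            if pfit.loglik_at_hat - pfit.loglik_at_zero >= gain - 1e-10:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
    return PhyloFit(
        lambda_hat=fit.lambda_hat,
        sigma2_hat=fit.sigma2_hat,
        root_state=fit.root_state,
        loglik_at_hat=fit.loglik_at_hat,
        loglik_at_zero=fit.loglik_at_zero,
        p_value=p,
        method=method,
        n_tips=fit.n_tips,
    )
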