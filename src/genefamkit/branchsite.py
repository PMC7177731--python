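"""Branch-site likelihood ratio test of episodic positive selection.

The model is the standard branch-site "model A": four site classes
(0, 1, 2a, 2b) with proportions (p0, p1, p2a, p2b), p2a/p2b = p0/p1;
background branches evolve with omega0 (< 1) on classes 0/2a and omega1 = 1
on classes 1/2b, while a designated *foreground* branch set evolves with
omega2 on classes 2a/2b. The null hypothesis fixes omega2 = 1 (relaxed
constraint only); the alternative lets omega2 >= 1 vary. Twice the
log-likelihood difference is referred to a chi-square with one degree of
freedom, and when the test is significant, positively selected sites are
identified by naive empirical Bayes: posterior P(class in {2a, 2b} | site)
at the alternative-model MLEs.

Likelihoods are computed with Felsenstein pruning over the shared GY94
engine (:mod:`genefamkit.codonmodel`); rate matrices are normalised so that
branch lengths are in expected substitutions per codon at the background
site-class mixture, matching the simulator's convention. Branch lengths are
taken as given (typically estimated once beforehand and fixed for both
hypotheses); an optional global scale factor can be optimised instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize

from . import codonmodel as cm
from .alignments import CodonAlignment
from .simulate import _node_id

_TINY = 1e-300


@dataclass
class BranchSiteModel:
    """Model-A parameter set."""

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float
    pi: np.ndarray
    foreground: frozenset = frozenset()

    def __post_init__(self):
        if not 0 < self.omega0 <= 1:
            raise ValueError("omega0 must be in (0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        if self.p0 <= 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("invalid class proportions")
        self.foreground = frozenset(self.foreground)

    @property
    def proportions(self) -> np.ndarray:
        """(p0, p1, p2a, p2b)."""
        p01 = self.p0 + self.p1
        p2 = max(0.0, 1.0 - p01)
        return np.array([self.p0, self.p1,
                         p2 * self.p0 / p01, p2 * self.p1 / p01])

    def class_omegas(self) -> list[tuple[float, float]]:
        """(background, foreground) omega per class 0, 1, 2a, 2b."""
        return [(self.omega0, self.omega0), (1.0, 1.0),
                (self.omega0, self.omega2), (1.0, self.omega2)]


@dataclass
class LRTOutcome:
    lnl_null: float
    lnl_alt: float
    statistic: float        # 2*(lnL_alt - lnL_null), clamped at 0
    p_value: float
    significant: bool
    alpha: float
    null_model: BranchSiteModel
    alt_model: BranchSiteModel
    neb_sites: list = field(default_factory=list)  # (site index, posterior)
    site_posteriors: np.ndarray | None = None
    #: True when nearly every site is assigned to class 2 at the MLE, in
    #: which case the NEB posterior is uninformative and no list is reported
    degenerate_site_posterior: bool = False


def chi2_sf_df1(x: float) -> float:
    """Upper tail of chi-square with 1 df (via the error function)."""
    if x <= 0:
        return 1.0
    return math.erfc(math.sqrt(x / 2.0))


class LikelihoodEngine:
    """Pruning-algorithm likelihood for one (tree, alignment) pair.

    Precomputes the traversal order and leaf partials once; each call to
    :meth:`loglikelihood` rebuilds only the rate matrices.
    """

    def __init__(self, tree: dendropy.Tree, aln: CodonAlignment,
                 foreground=frozenset()):
        self.tree = tree
        self.aln = aln
        leaves = [lf for lf in tree.leaf_node_iter()]
        tree_ids = {lf.taxon.label for lf in leaves}
        if tree_ids != set(aln.ids):
            raise ValueError("tree leaves and alignment ids differ: "
                             f"{sorted(tree_ids ^ set(aln.ids))}")
        self.states = aln.codon_state_matrix()
        self.n_sites = aln.n_codons
        self.postorder = [n for n in tree.postorder_node_iter()]
        for node in self.postorder:
            if node is not tree.seed_node and (node.edge.length or 0.0) < 0:
                raise ValueError("negative branch length")
        self.foreground = frozenset(foreground)
        known = {_node_id(n) for n in self.postorder if _node_id(n)}
        unknown = self.foreground - known
        if unknown:
            raise ValueError(f"foreground branches not in tree: {sorted(unknown)}")
        # leaf partials: one-hot with gaps as all-ones
        self._leaf_partial = {}
        row_of = {sid: i for i, sid in enumerate(aln.ids)}
        for lf in leaves:
            s = self.states[row_of[lf.taxon.label]]
            P = np.zeros((cm.N_CODONS, self.n_sites))
            obs = s >= 0
            P[s[obs], np.flatnonzero(obs)] = 1.0
            P[:, ~obs] = 1.0
            self._leaf_partial[lf] = P

    def site_class_likelihoods(self, model: BranchSiteModel,
                               scale: float = 1.0) -> np.ndarray:
        """(4, n_sites) per-class site likelihoods (natural scale, with a
        per-site log offset folded back in; see loglikelihood)."""
        L, _ = self._class_likelihoods(model, scale)
        return L

    def _class_likelihoods(self, model: BranchSiteModel, scale: float):
        pi = model.pi
        props = model.proportions
        bg_omegas = [model.omega0, 1.0, model.omega0, 1.0]
        rate_scale = cm.mixture_scale(model.kappa, bg_omegas, props, pi)
        mats = {}
        for w in {model.omega0, 1.0, model.omega2}:
            mats[w] = cm.ReversibleCodonMatrix(
                cm.rate_matrix(model.kappa, w, pi) / rate_scale, pi)
        P_cache: dict[tuple[float, float], np.ndarray] = {}

        def P(w, t):
            key = (w, t)
            if key not in P_cache:
                P_cache[key] = mats[w].transition_matrix(t)
            return P_cache[key]

        class_site_L = np.empty((4, self.n_sites))
        log_offsets = np.zeros((4, self.n_sites))
        done: dict[tuple, int] = {}  # classes sharing (bg, fg) omegas prune once
        for k, (bg_w, fg_w) in enumerate(model.class_omegas()):
            if (bg_w, fg_w) in done:
                j = done[(bg_w, fg_w)]
                class_site_L[k] = class_site_L[j]
                log_offsets[k] = log_offsets[j]
                continue
            done[(bg_w, fg_w)] = k
            partial = {}
            offset = np.zeros(self.n_sites)
            for node in self.postorder:
                if node.is_leaf():
                    partial[node] = self._leaf_partial[node]
                    continue
                acc = None
                for child in node.child_nodes():
                    w = fg_w if _node_id(child) in model.foreground else bg_w
                    t = (child.edge.length or 0.0) * scale
                    term = P(w, t).T @ partial[child]
                    acc = term if acc is None else acc * term
                    del partial[child]
                # rescale to avoid underflow on deep trees
                m = acc.max(axis=0)
                m[m <= 0] = 1.0
                acc /= m
                offset += np.log(m)
                partial[node] = acc
            root = self.postorder[-1]
            class_site_L[k] = pi @ partial[root]
            log_offsets[k] = offset
        return class_site_L, log_offsets

    def loglikelihood(self, model: BranchSiteModel, scale: float = 1.0) -> float:
        L, off = self._class_likelihoods(model, scale)
        props = model.proportions
        # per-class offsets differ; combine on the log scale per site
        ref = off.max(axis=0)
        mix = (props[:, None] * L * np.exp(off - ref)).sum(axis=0)
        if np.any(mix <= 0):
            bad = int(np.argmax(mix <= 0))
            raise FloatingPointError(f"non-finite likelihood at site {bad}")
        return float(np.sum(np.log(mix) + ref))

    def site_posteriors(self, model: BranchSiteModel,
                        scale: float = 1.0) -> np.ndarray:
        """(4, n_sites) naive-empirical-Bayes class posteriors."""
        L, off = self._class_likelihoods(model, scale)
        props = model.proportions
        ref = off.max(axis=0)
        w = props[:, None] * L * np.exp(off - ref)
        return w / w.sum(axis=0, keepdims=True)


def codon_loglikelihood(tree: dendropy.Tree, aln: CodonAlignment,
                        model: BranchSiteModel) -> float:
    """Log-likelihood of the alignment under ``model`` (one-shot API)."""
    if aln.n_sequences == 1:
        # no evolution: the likelihood is the stationary probability of
        # every observed codon
        states = aln.codon_state_matrix()[0]
        return float(np.sum(np.log(model.pi[states[states >= 0]])))
    return LikelihoodEngine(tree, aln, model.foreground).loglikelihood(model)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _unpack(x, pi, foreground, alternative: bool) -> BranchSiteModel:
    kappa = math.exp(x[0])
    omega0 = 1e-5 + (1 - 2e-5) * _sigmoid(x[1])
    p01 = 1e-6 + (1 - 2e-6) * _sigmoid(x[2])
    ratio = 1e-6 + (1 - 2e-6) * _sigmoid(x[3])
    omega2 = 1.0 + math.exp(x[4]) if alternative else 1.0
    return BranchSiteModel(kappa=kappa, omega0=omega0, omega2=omega2,
                           p0=p01 * ratio, p1=p01 * (1 - ratio), pi=pi,
                           foreground=foreground)


def _pack(model: BranchSiteModel, alternative: bool) -> np.ndarray:
    p01 = model.p0 + model.p1
    x = [math.log(model.kappa), _logit(model.omega0), _logit(min(p01, 1 - 1e-9)),
         _logit(model.p0 / p01)]
    if alternative:
        x.append(math.log(max(model.omega2 - 1.0, 1e-6)))
    return np.array(x)


_BOUNDS = [(-3.0, 5.0),    # log kappa
           (-12.0, 12.0),  # logit omega0
           (-12.0, 12.0),  # logit (p0 + p1)
           (-12.0, 12.0),  # logit p0/(p0+p1)
           (-8.0, 6.0)]    # log (omega2 - 1)


def _fit(engine: LikelihoodEngine, pi, foreground, alternative: bool,
         starts: list[np.ndarray], tol: float = 1e-8):
    def objective(x):
        model = _unpack(x, pi, foreground, alternative)
        try:
            return -engine.loglikelihood(model)
        except FloatingPointError:
            return 1e12

    bounds = _BOUNDS[:5] if alternative else _BOUNDS[:4]
    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": tol, "maxiter": 300,
                                         "eps": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("optimizer failed: non-finite likelihood; "
                           f"best x = {best.x}")
    model = _unpack(best.x, pi, foreground, alternative)
    return model, -float(best.fun)


def branch_site_test(tree: dendropy.Tree, aln: CodonAlignment,
                     foreground, alpha: float = 0.05,
                     pi: np.ndarray | None = None,
                     n_starts: int = 1, seed: int = 0,
                     neb_threshold: float = 0.95) -> LRTOutcome:
    """Branch-site LRT of positive selection on ``foreground`` branches.

    ``foreground`` is a branch id (head-node label or leaf label) or an
    iterable of them. Codon frequencies default to F3x4 estimated from the
    alignment. The null model (omega2 = 1) is fitted first from ``n_starts``
    starting points; the alternative is warm-started at the null optimum
    (guaranteeing lnL_alt >= lnL_null up to optimizer tolerance) plus
    ``n_starts - 1`` perturbed starts.
    """
    if isinstance(foreground, str):
        foreground = {foreground}
    foreground = frozenset(foreground)
    if pi is None:
        pi = cm.empirical_f3x4(CodonAlignment(aln.ids, aln.rows).codon_state_matrix())
    engine = LikelihoodEngine(tree, aln, foreground)
    rng = np.random.default_rng(seed)

    base = BranchSiteModel(kappa=2.0, omega0=0.3, omega2=1.0,
                           p0=0.6, p1=0.25, pi=pi, foreground=foreground)
    null_starts = [_pack(base, alternative=False)]
    for _ in range(n_starts - 1):
        null_starts.append(null_starts[0] + rng.normal(0, 1.0, size=4))
    null_model, lnl_null = _fit(engine, pi, foreground, False, null_starts)

    # the alternative surface has a known degenerate corner (p0 = p1 = 0,
    # all sites class 2 with modest omega2); structured starts spanning low
    # and high omega2 from both the null optimum and a generic interior
    # point keep the optimizer out of it
    def warm(omega2, m=null_model):
        return _pack(BranchSiteModel(
            kappa=m.kappa, omega0=m.omega0, omega2=omega2,
            p0=m.p0, p1=m.p1, pi=pi, foreground=foreground),
            alternative=True)

    alt_starts = [warm(2.0), warm(8.0), warm(4.0, base)]
    for _ in range(n_starts - 1):
        alt_starts.append(alt_starts[0] + rng.normal(0, 1.0, size=5))
    alt_model, lnl_alt = _fit(engine, pi, foreground, True, alt_starts)
    if alt_model.p0 + alt_model.p1 < 0.05:
        # the corner won: rescue with interior proportions at the fitted
        # kappa/omega values and keep whichever likelihood is higher
        rescue = _pack(BranchSiteModel(
            kappa=alt_model.kappa, omega0=alt_model.omega0,
            omega2=max(alt_model.omega2, 4.0), p0=0.6, p1=0.25, pi=pi,
            foreground=foreground), alternative=True)
        resc_model, resc_lnl = _fit(engine, pi, foreground, True, [rescue])
        if resc_lnl > lnl_alt:
            alt_model, lnl_alt = resc_model, resc_lnl

    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    lnl_alt = max(lnl_alt, lnl_null)  # nesting after clamping
    p = chi2_sf_df1(stat)
    significant = p <= alpha

    neb_sites = []
    posteriors = None
    degenerate = False
    if significant:
        posteriors = engine.site_posteriors(alt_model)
        pos = posteriors[2] + posteriors[3]
        p2_hat = float(alt_model.proportions[2] + alt_model.proportions[3])
        if p2_hat >= 0.9:
            # nearly all sites assigned to class 2 at the MLE: the NEB
            # posterior cannot discriminate sites, so no list is reported
            degenerate = True
        else:
            neb_sites = [(int(i), float(pos[i]))
                         for i in np.flatnonzero(pos >= neb_threshold)]
    return LRTOutcome(lnl_null=lnl_null, lnl_alt=lnl_alt, statistic=stat,
                      p_value=p, significant=significant, alpha=alpha,
                      null_model=null_model, alt_model=alt_model,
                      neb_sites=neb_sites, site_posteriors=posteriors,
                      degenerate_site_posterior=degenerate)


def foreground_from_labels(tree: dendropy.Tree) -> frozenset:
    """Read foreground branches from the common ``#1`` Newick label dialect.

    Labels (taxon or internal) ending in ``#1`` mark foreground branches;
    the suffix is stripped in place and the branch id set returned.
    """
    marked = set()
    for node in tree.preorder_node_iter():
        for holder in (node.taxon, node):
            label = getattr(holder, "label", None)
            if label and label.rstrip().endswith("#1"):
                clean = label.rstrip()[:-2].strip()
                holder.label = clean
                marked.add(clean)
    return frozenset(marked)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional correction across many branch tests;
    off by default in the pipeline, matching per-test alpha reporting)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj
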