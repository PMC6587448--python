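"""Codon-model selection scan: branch and branch-site dN/dS tests.

The substitution process is the Goldman-Yang codon model (61 sense codons,
transition/transversion ratio kappa, dN/dS ratio omega, equilibrium codon
frequencies from the alignment, F3x4 by default). Log-likelihoods are
computed by Felsenstein pruning with per-pattern scaling; gaps and
ambiguous codons are treated as missing data.

Model hierarchy for the branch tests on a tree whose foreground branch is
tagged ``#1`` (PAML convention):

* H0 / M0 — one omega for every branch;
* H1 / two-ratio — one foreground omega, one background omega;
* H2 / free-ratio — an independent omega on every branch.

Fast-evolving genes are those where H1 significantly beats H0, H2 does not
significantly beat H1, and the foreground omega exceeds the background
(FDR-adjusted p < alpha, Benjamini-Hochberg). Positive selection on sites
of the foreground branch uses branch-site Model A: the alternative frees
omega2 >= 1 on the foreground site classes, the null fixes omega2 = 1;
genes with an FDR-adjusted p < alpha and omega2 > 1 are called positively
selected. Nei-Gojobori (1986) pathway counting provides a model-free omega
estimate used as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from . import _codon
from ._trees import edge_key, parse_foreground_tree, parse_newick
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

MODELS = ("M0", "branch_2ratio", "branch_free", "branchsite_null", "branchsite_alt")

build_codon_matrix = _codon.build_codon_rate_matrix


# ---------------------------------------------------------------------------
# likelihood engine


class _CodonLikelihood:
    """Pruning log-likelihood of a codon alignment on a fixed topology.

    Site patterns are compressed once; eigendecompositions of the rate
    matrix are cached per (kappa, omega), so evaluations that only move
    branch lengths are cheap.
    """

    def __init__(self, alignment: dict[str, str], tree, codon_frequencies):
        if isinstance(tree, str):
            tree = parse_newick(tree)
        tree = tree.clone(depth=1)
        if len(tree.seed_node.child_nodes()) == 2 and len(tree.leaf_nodes()) > 2:
            tree.deroot()
        self.tree = tree
        self.pi = np.asarray(codon_frequencies, dtype=float)
        self.taxa = sorted(alignment)
        tree_taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if set(self.taxa) != tree_taxa:
            raise InputError(
                f"alignment taxa {self.taxa} do not match tree taxa {sorted(tree_taxa)}"
            )
        coded = np.vstack([_codon.encode_codons(alignment[t]) for t in self.taxa])
        pats, inverse, counts = np.unique(
            coded, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = pats  # (ntaxa, npat)
        self.counts = counts.astype(float)
        self.n_sites = coded.shape[1]
        self.taxon_row = {t: i for i, t in enumerate(self.taxa)}

        self.postorder = [
            n for n in tree.postorder_node_iter() if n is not tree.seed_node
        ]
        self.edge_index = {id(n): k for k, n in enumerate(self.postorder)}
        self.edge_keys = [edge_key(n) for n in self.postorder]
        self.n_edges = len(self.postorder)
        self._eigcache: dict[tuple, _codon.CodonEigen] = {}

    def _eigen(self, kappa: float, omega: float) -> _codon.CodonEigen:
        key = (round(float(kappa), 10), round(float(omega), 10))
        if key not in self._eigcache:
            if len(self._eigcache) > 128:
                self._eigcache.clear()
            self._eigcache[key] = _codon.CodonEigen(kappa, omega, self.pi)
        return self._eigcache[key]

    def edge_foreground_mask(self, foreground) -> np.ndarray:
        """Boolean per-edge mask for a set of foreground edge keys; a key
        may also match the complement clade (the tree is unrooted)."""
        all_leaves = frozenset(t for t in self.taxa)
        mask = np.zeros(self.n_edges, dtype=bool)
        for k, ek in enumerate(self.edge_keys):
            clade = frozenset([ek]) if isinstance(ek, str) else ek
            comp = all_leaves - clade
            for key in foreground:
                fk = frozenset([key]) if isinstance(key, str) else frozenset(key)
                if clade == fk or comp == fk:
                    mask[k] = True
        return mask

    def loglikelihood(
        self, kappa, branch_lengths, omega_by_class, class_props=None
    ) -> float:
        """lnL for per-class, per-edge omegas mixed with class proportions.

        ``omega_by_class`` has shape (n_classes, n_edges);
        ``class_props`` sums to 1 (defaults to a single class).
        """
        omega_by_class = np.atleast_2d(np.asarray(omega_by_class, dtype=float))
        n_class = omega_by_class.shape[0]
        if class_props is None:
            class_props = np.ones(n_class) / n_class if n_class > 1 else np.ones(1)
        class_props = np.asarray(class_props, dtype=float)
        t = np.asarray(branch_lengths, dtype=float)
        npat = self.patterns.shape[1]

        if self.n_edges == 0:  # single-taxon "tree": lnL = sum log pi(codon)
            states = self.patterns[0]
            site = np.where(states >= 0, np.log(self.pi[np.maximum(states, 0)]), 0.0)
            return float(np.sum(self.counts * site))

        # one time scale per edge: the class-averaged substitution rate, so
        # rate differences between site classes are preserved
        edge_rate = np.empty(self.n_edges)
        for k in range(self.n_edges):
            mus = np.array(
                [self._eigen(kappa, omega_by_class[c, k]).rate for c in range(n_class)]
            )
            edge_rate[k] = float(class_props @ mus)

        log_class = np.empty((n_class, npat))
        for c in range(n_class):
            messages: dict[int, np.ndarray] = {}
            logscale = np.zeros(npat)
            for k, node in enumerate(self.postorder):
                P = self._eigen(kappa, omega_by_class[c, k]).transition_matrix(
                    t[k], rate=edge_rate[k]
                )
                if node.is_leaf():
                    states = self.patterns[self.taxon_row[node.taxon.label]]
                    msg = np.ones((_codon.N_CODONS, npat))
                    obs = states >= 0
                    msg[:, obs] = P[:, states[obs]]
                else:
                    partial = np.ones((_codon.N_CODONS, npat))
                    for child in node.child_nodes():
                        partial *= messages.pop(id(child))
                    m = partial.max(axis=0)
                    safe = np.where(m > 0, m, 1.0)
                    partial /= safe
                    logscale += np.log(safe)
                    msg = P @ partial
                messages[id(node)] = msg
            partial = np.ones((_codon.N_CODONS, npat))
            for child in self.tree.seed_node.child_nodes():
                partial *= messages.pop(id(child))
            with np.errstate(divide="ignore"):
                log_class[c] = np.log(self.pi @ partial) + logscale
        with np.errstate(divide="ignore"):
            weighted = log_class + np.log(class_props)[:, None]
        site_log = np.max(weighted, axis=0)
        with np.errstate(invalid="ignore"):
            site_log = site_log + np.log(
                np.sum(np.exp(weighted - site_log[None, :]), axis=0)
            )
        if np.any(~np.isfinite(site_log)):
            return -np.inf
        return float(np.sum(self.counts * site_log))


def pruning_loglikelihood(
    alignment: dict[str, str],
    tree,
    kappa: float,
    omega,
    codon_frequencies=None,
    branch_lengths=None,
) -> float:
    """Felsenstein-pruning lnL at fixed parameters.

    ``omega`` is a scalar or a per-branch dict (keyed like
    :func:`panforge._trees.edge_key`); branch lengths default to the tree's
    own; frequencies default to F3x4 estimated from the alignment.
    """
    if codon_frequencies is None:
        codon_frequencies = _codon.empirical_codon_frequencies(
            alignment.values(), "F3x4"
        )
    lik = _CodonLikelihood(alignment, tree, codon_frequencies)
    if branch_lengths is None:
        t = np.array([n.edge.length or 0.0 for n in lik.postorder])
    else:
        t = np.asarray(branch_lengths, dtype=float)
    from ._trees import lookup_branch_value

    om = np.array(
        [
            float(lookup_branch_value(ek, omega, default=np.nan))
            for ek in lik.edge_keys
        ]
    )
    if np.any(np.isnan(om)):
        raise ConfigurationError("omega missing for some branch")
    return lik.loglikelihood(kappa, t, om[None, :])


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class CodonModelResults:
    """Fitted codon model: estimates, likelihood and bookkeeping."""

    model: str
    lnL: float
    kappa: float
    omega_estimates: dict
    branch_lengths: dict
    codon_frequencies: np.ndarray
    converged: bool
    n_params: int
    n_iter: int = 0
    site_class_proportions: dict = field(default_factory=dict)

    @property
    def omega_foreground(self):
        return self.omega_estimates.get("foreground")

    @property
    def omega_background(self):
        return self.omega_estimates.get("background")

    def summary(self) -> str:
        lines = [
            f"Codon model fit: {self.model}",
            "=" * 40,
            f"lnL        {self.lnL:.6f}",
            f"kappa      {self.kappa:.4f}",
            f"n_params   {self.n_params}",
            f"converged  {self.converged}",
        ]
        for name, val in self.omega_estimates.items():
            lines.append(f"omega[{name}]  {val:.4f}")
        for name, val in self.site_class_proportions.items():
            lines.append(f"p[{name}]   {val:.4f}")
        tree_len = sum(self.branch_lengths.values())
        lines.append(f"tree length {tree_len:.4f} (substitutions/codon)")
        return "\n".join(lines)


class CodonModel:
    """A codon substitution model bound to one alignment and tree.

    ``tree`` may carry PAML-style ``#1`` tags marking the foreground
    branch(es); alternatively pass ``foreground`` as a set of edge keys
    (leaf label, or frozenset of descendant leaf labels). ``fit`` maximises
    the likelihood over kappa, the model's omegas (and site-class
    proportions for branch-site models) and all branch lengths.
    """

    def __init__(
        self,
        alignment: dict[str, str],
        tree,
        model: str = "M0",
        foreground=None,
        codon_freq: str = "F3x4",
        kappa_init: float = 2.5,
        omega_init: float = 0.2,
    ):
        if model not in MODELS:
            raise ConfigurationError(f"unknown model {model!r}; one of {MODELS}")
        if isinstance(tree, str):
            tree, tagged = parse_foreground_tree(tree)
            if foreground is None and tagged:
                foreground = tagged
        self.model = model
        self.alignment = dict(alignment)
        if codon_freq in ("F3x4", "F1x4"):
            self.pi = _codon.empirical_codon_frequencies(
                self.alignment.values(), codon_freq
            )
        else:
            self.pi = np.asarray(codon_freq, dtype=float)
        self.lik = _CodonLikelihood(self.alignment, tree, self.pi)
        self.kappa_init = kappa_init
        self.omega_init = omega_init
        needs_fg = model in ("branch_2ratio", "branchsite_null", "branchsite_alt")
        if needs_fg:
            if not foreground:
                raise ConfigurationError(f"model {model} requires a foreground branch")
            self.fg_mask = self.lik.edge_foreground_mask(foreground)
            if not self.fg_mask.any():
                raise ConfigurationError("foreground branch not found in tree")
        else:
            self.fg_mask = np.zeros(self.lik.n_edges, dtype=bool)

    # -- parameter packing ---------------------------------------------------

    def _t_init(self) -> np.ndarray:
        t = np.array([n.edge.length or 0.0 for n in self.lik.postorder])
        t[t <= 0] = 0.05
        return t

    def _spec(self):
        """(x0, bounds, unpack) for the chosen model."""
        ne = self.lik.n_edges
        t0 = self._t_init()
        t_bounds = [(1e-6, 50.0)] * ne
        k_bound = (0.2, 50.0)
        w_bound = (1e-4, 99.0)
        fg = self.fg_mask

        if self.model == "M0":
            x0 = np.concatenate([[self.kappa_init, self.omega_init], t0])
            bounds = [k_bound, w_bound] + t_bounds

            def unpack(x):
                om = np.full((1, ne), x[1])
                return x[0], x[2:], om, np.ones(1), {"all": x[1]}, {}

        elif self.model == "branch_2ratio":
            x0 = np.concatenate(
                [[self.kappa_init, self.omega_init, self.omega_init], t0]
            )
            bounds = [k_bound, w_bound, w_bound] + t_bounds

            def unpack(x):
                om = np.where(fg, x[2], x[1])[None, :]
                return (
                    x[0],
                    x[3:],
                    om,
                    np.ones(1),
                    {"background": x[1], "foreground": x[2]},
                    {},
                )

        elif self.model == "branch_free":
            x0 = np.concatenate(
                [[self.kappa_init], np.full(ne, self.omega_init), t0]
            )
            bounds = [k_bound] + [w_bound] * ne + t_bounds

            def unpack(x):
                om = x[1 : 1 + ne][None, :]
                omega_named = {
                    self._edge_name(k): float(x[1 + k]) for k in range(ne)
                }
                return x[0], x[1 + ne :], om, np.ones(1), omega_named, {}

        else:  # branch-site Model A (null: omega2 fixed at 1; alt: free >= 1)
            alt = self.model == "branchsite_alt"
            # q0: p0/(p0+p1); q1: p0+p1; omega0 in (0,1); omega2
            x0 = [self.kappa_init, 0.5, 0.85, min(self.omega_init, 0.9)]
            bounds = [k_bound, (1e-3, 1 - 1e-3), (1e-3, 1 - 1e-3), (1e-4, 0.999)]
            if alt:
                x0.append(1.5)
                bounds.append((1.0, 99.0))
            x0 = np.concatenate([x0, t0])
            bounds = bounds + t_bounds
            n_head = 5 if alt else 4

            def unpack(x, alt=alt, n_head=n_head):
                kappa, q0, q1, w0 = x[0], x[1], x[2], x[3]
                w2 = x[4] if alt else 1.0
                t = x[n_head:]
                p0, p1 = q1 * q0, q1 * (1 - q0)
                p2 = 1 - q1
                props = np.array([p0, p1, p2 * q0, p2 * (1 - q0)])
                om = np.empty((4, ne))
                om[0] = w0
                om[1] = 1.0
                om[2] = np.where(fg, w2, w0)
                om[3] = np.where(fg, w2, 1.0)
                omega_named = {"omega0": float(w0), "omega2": float(w2)}
                pnames = dict(zip(("p0", "p1", "p2a", "p2b"), map(float, props)))
                return kappa, t, om, props, omega_named, pnames

        return np.asarray(x0, dtype=float), bounds, unpack

    def _edge_name(self, k):
        ek = self.lik.edge_keys[k]
        return ek if isinstance(ek, str) else "(" + ",".join(sorted(ek)) + ")"

    # -- fitting ---------------------------------------------------------------

    def fit(self, maxiter: int = 300, gtol: float = 1e-6, restarts: int = 1):
        x0, bounds, unpack = self._spec()

        def negloglik(x):
            kappa, t, om, props, *_ = unpack(x)
            val = self.lik.loglikelihood(kappa, t, om, props)
            return -val if np.isfinite(val) else 1e12

        starts = [x0]
        if self.model == "branchsite_alt":
            # omega2 sits on a boundary under the null; also start just
            # above 1 so the alternative can never undershoot the null
            near_null = x0.copy()
            near_null[4] = 1.0 + 1e-4
            high = x0.copy()
            high[4] = 4.0
            starts += [near_null, high]
        best = None
        n_iter = 0
        for start in starts:
            res = minimize(
                negloglik,
                start,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
            )
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
        for attempt in range(restarts):
            if best.success:
                break
            res = minimize(
                negloglik,
                np.clip(
                    x0 * 1.3 + 0.01, [b[0] for b in bounds], [b[1] for b in bounds]
                ),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
            )
            n_iter += res.nit
            if res.fun < best.fun:
                best = res
        kappa, t, _om, _props, omega_named, pnames = unpack(best.x)
        n_params = len(best.x)
        branch_named = {
            self._edge_name(k): float(t[k]) for k in range(self.lik.n_edges)
        }
        return CodonModelResults(
            model=self.model,
            lnL=float(-best.fun),
            kappa=float(kappa),
            omega_estimates=omega_named,
            branch_lengths=branch_named,
            codon_frequencies=self.pi,
            converged=bool(best.success),
            n_params=int(n_params),
            n_iter=int(n_iter),
            site_class_proportions=pnames,
        )


def fit_model(
    alignment,
    tree,
    model_spec: str,
    foreground=None,
    kappa_init: float = 2.5,
    omega_init: float = 0.2,
    codon_freq: str = "F3x4",
) -> CodonModelResults:
    """Convenience wrapper: build a :class:`CodonModel` and fit it."""
    return CodonModel(
        alignment,
        tree,
        model=model_spec,
        foreground=foreground,
        codon_freq=codon_freq,
        kappa_init=kappa_init,
        omega_init=omega_init,
    ).fit()


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986 counting (independent omega oracle)


def _codon_site_counts(codon: str) -> tuple[float, float]:
    syn = 0.0
    for k in range(3):
        for alt in "TCAG":
            if alt == codon[k]:
                continue
            mutant = codon[:k] + alt + codon[k + 1 :]
            if mutant in _codon.STOP_CODONS:
                continue  # counted as nonsynonymous
            if _codon.CODON_AA[mutant] == _codon.CODON_AA[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over all substitution
    orders between two codons, skipping pathways through stop codons."""
    positions = _codon.codon_diffs(c1, c2)
    if not positions:
        return 0.0, 0.0
    results = []
    for order in permutations(positions):
        cur = c1
        syn = nsyn = 0
        ok = True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1 :]
            if nxt in _codon.STOP_CODONS:
                ok = False
                break
            if _codon.CODON_AA[cur] == _codon.CODON_AA[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nsyn))
    if not results:  # all pathways blocked by stops; count direct as nonsyn
        return 0.0, float(len(positions))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def ng86_dnds(cds_a: str, cds_b: str) -> dict:
    """Nei-Gojobori (1986) dN/dS between two equal-length gap-free CDS.

    Synonymous/nonsynonymous site counts are averaged over the two
    sequences, difference counts are pathway-averaged, and both proportions
    receive the Jukes-Cantor correction. ``omega`` is NaN with
    ``undefined=True`` when dS = 0.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b) or len(a) % 3:
        raise InputError("sequences must be equal-length, in-frame")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        for c in (ca, cb):
            if c in _codon.STOP_CODONS:
                raise InputError(f"stop codon at position {i}")
            if c not in _codon.CODON_INDEX:
                raise InputError(f"ambiguous codon {c!r} at position {i}")
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p):
        if p >= 0.75:
            return np.inf
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = jc(pS), jc(pN)
    undefined = dS == 0.0
    omega = float("nan") if undefined else dN / dS
    return {
        "dN": float(dN),
        "dS": float(dS),
        "omega": omega,
        "S": S,
        "N": N,
        "Sd": Sd,
        "Nd": Nd,
        "undefined": bool(undefined),
    }


# ---------------------------------------------------------------------------
# tests and calls


def lrt(lnL_null: float, lnL_alt: float, df: int, tolerance: float = 1e-4) -> float:
    """Likelihood-ratio test p-value: p = P(chi2_df >= 2 * (alt - null)).

    A slightly negative statistic (within ``tolerance``, from numerical
    optimisation) is clamped to zero.
    """
    if df <= 0:
        raise InputError("df must be positive")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < -tolerance:
        raise InputError(
            f"alternative lnL below null beyond tolerance (2dl = {stat:.4g})"
        )
    return float(chi2.sf(max(stat, 0.0), df))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_fast_evolving(fits: dict, alpha: float = 0.01) -> pd.DataFrame:
    """Fast-evolving calls from per-family H0/H1/H2 fits.

    ``fits`` maps family id to a dict with keys ``H0``, ``H1``, ``H2``
    (:class:`CodonModelResults`). A family is fast-evolving when the
    FDR-adjusted p of H1 vs H0 (df=1) is < alpha, the adjusted p of H2 vs
    H1 (df = n_branches - 2) is >= alpha, and the foreground omega exceeds
    the background. Unconverged families are excluded (logged).
    """
    rows = []
    for fam in sorted(fits):
        f = fits[fam]
        if not all(f[m].converged for m in ("H0", "H1", "H2")):
            logger.warning("family %s excluded: unconverged fit", fam)
            continue
        n_branches = len(f["H2"].branch_lengths)
        df2 = max(n_branches - 2, 1)
        rows.append(
            {
                "family_id": fam,
                "lnL_H0": f["H0"].lnL,
                "lnL_H1": f["H1"].lnL,
                "lnL_H2": f["H2"].lnL,
                "omega_foreground": f["H1"].omega_foreground,
                "omega_background": f["H1"].omega_background,
                "p_H1_vs_H0": lrt(f["H0"].lnL, f["H1"].lnL, 1),
                "p_H2_vs_H1": lrt(f["H1"].lnL, f["H2"].lnL, df2),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["q_H1_vs_H0"] = df["q_H2_vs_H1"] = df["fast_evolving"] = []
        return df
    df["q_H1_vs_H0"] = bh_adjust(df["p_H1_vs_H0"])
    df["q_H2_vs_H1"] = bh_adjust(df["p_H2_vs_H1"])
    df["fast_evolving"] = (
        (df["q_H1_vs_H0"] < alpha)
        & (df["q_H2_vs_H1"] >= alpha)
        & (df["omega_foreground"] > df["omega_background"])
    )
    return df.sort_values("family_id").reset_index(drop=True)


def classify_positively_selected(fits: dict, alpha: float = 0.01) -> pd.DataFrame:
    """Positive-selection calls from per-family branch-site null/alt fits.

    A family is called when the FDR-adjusted p of alt vs null (df=1) is
    < alpha and the foreground site-class omega2 exceeds 1.
    """
    rows = []
    for fam in sorted(fits):
        f = fits[fam]
        if not (f["null"].converged and f["alt"].converged):
            logger.warning("family %s excluded: unconverged branch-site fit", fam)
            continue
        rows.append(
            {
                "family_id": fam,
                "lnL_bs_null": f["null"].lnL,
                "lnL_bs_alt": f["alt"].lnL,
                "omega2": f["alt"].omega_estimates["omega2"],
                "p_bs": lrt(f["null"].lnL, f["alt"].lnL, 1),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["q_bs"] = df["positively_selected"] = []
        return df
    df["q_bs"] = bh_adjust(df["p_bs"])
    df["positively_selected"] = (df["q_bs"] < alpha) & (df["omega2"] > 1.0)
    return df.sort_values("family_id").reset_index(drop=True)


def combine_calls(fast_df: pd.DataFrame, ps_df: pd.DataFrame) -> pd.DataFrame:
    """Merge the two screens into one call per family:
    fast_evolving, positively_selected, both, or neither."""
    merged = pd.merge(
        fast_df[["family_id", "fast_evolving"]],
        ps_df[["family_id", "positively_selected"]],
        on="family_id",
        how="outer",
    ).fillna(False)

    def call(row):
        if row.fast_evolving and row.positively_selected:
            return "both"
        if row.fast_evolving:
            return "fast_evolving"
        if row.positively_selected:
            return "positively_selected"
        return "neither"

    merged["call"] = merged.apply(call, axis=1)
    return merged.sort_values("family_id").reset_index(drop=True)
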