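"""Partitioned maximum-likelihood engine.

Felsenstein pruning over mixed 4-state / doublet partitions that share one
set of branch lengths, with per-partition rate multipliers (first fixed to
1), discrete-gamma rate variation (4 categories), coordinate-wise branch
length optimization, bounded multivariate model-parameter optimization,
exhaustive quartet search and NNI hill climbing, and AICc scoring.

Ambiguity (gaps, Ns, IUPAC codes, mismatch doublets under 6-state models)
enters as partial-likelihood masks at the tips.  Per-node rescaling keeps
partial likelihoods in range for large trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from . import trees as _trees
from .models import (ModelSpec, build_rate_matrix, count_free_parameters,
                     default_parameters, discretize_gamma, get_model,
                     project_frequencies)
from .structure import (encode_doublet, encode_nucleotide,
                        partition_alignment)

log = logging.getLogger(__name__)

_BL_BOUNDS = (1e-8, 20.0)
_LOG_RATE_BOUNDS = (-7.0, 7.0)
_LOG_ALPHA_BOUNDS = (np.log(0.02), np.log(50.0))


class LikelihoodError(ValueError):
    pass


class SetupError(ValueError):
    pass


# ---------------------------------------------------------------------------
# encoded partitions

@dataclass
class EncodedPartition:
    """Site patterns of one partition plus its model and parameters.

    ``tips`` has shape (n_taxa, n_patterns, n_states) with 0/1 ambiguity
    masks; ``n_columns`` is the partition's observation count for AICc
    (loop columns, or stem doublets).
    """

    name: str
    spec: ModelSpec
    tips: np.ndarray
    weights: np.ndarray
    n_columns: int
    exch: np.ndarray = None
    freqs: np.ndarray = None
    alpha: float = 0.5
    multiplier: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        d_exch, d_freqs = default_parameters(self.spec)
        if self.exch is None:
            self.exch = d_exch
        if self.freqs is None:
            self.freqs = d_freqs
        self.exch = np.asarray(self.exch, dtype=float)
        self.freqs = project_frequencies(self.spec, self.freqs)

    def rate_matrix(self):
        # parameters change rarely relative to likelihood evaluations
        key = (self.exch.tobytes(), self.freqs.tobytes())
        cached = getattr(self, "_rm_cache", None)
        if cached is None or cached[0] != key:
            rm = build_rate_matrix(self.spec, self.exch, self.freqs)
            rm.decomposition()
            self._rm_cache = (key, rm)
        return self._rm_cache[1]

    def clone(self):
        return replace(self, exch=self.exch.copy(), freqs=self.freqs.copy())


def _compress(tip_masks: np.ndarray):
    """Collapse identical site patterns; ambiguity-distinct patterns stay
    distinct.  Input (n_taxa, n_cols, n_states) -> (tips, weights)."""
    n_taxa, n_cols, n_states = tip_masks.shape
    flat = np.ascontiguousarray(tip_masks.transpose(1, 0, 2).reshape(n_cols, -1))
    uniq, counts = np.unique(flat, axis=0, return_counts=True)
    tips = uniq.reshape(-1, n_taxa, n_states).transpose(1, 0, 2)
    return np.ascontiguousarray(tips, dtype=float), counts.astype(float)


def encode_loop_partition(matrix: np.ndarray, name="loops", spec=None,
                          **params) -> EncodedPartition:
    """Encode nucleotide columns (n_taxa, m) as a 4-state partition."""
    spec = spec or get_model("GTR")
    n_taxa, m = matrix.shape
    masks = np.zeros((n_taxa, m, 4), dtype=np.uint8)
    for t in range(n_taxa):
        for c in range(m):
            idx = encode_nucleotide(matrix[t, c], context=f"row {t}, col {c + 1}")
            masks[t, c, list(idx)] = 1
    tips, weights = _compress(masks)
    return EncodedPartition(name=name, spec=spec, tips=tips, weights=weights,
                            n_columns=m, **params)


def encode_stem_partition(aln_matrix: np.ndarray, stem_pairs, spec,
                          name="stems", **params) -> EncodedPartition:
    """Encode paired columns as doublet sites in the spec's state space."""
    n_states = spec.n_states
    n_taxa = aln_matrix.shape[0]
    m = len(stem_pairs)
    if m == 0:
        raise SetupError(f"empty stem partition but RNA model {spec.name} requested")
    masks = np.zeros((n_taxa, m, n_states), dtype=np.uint8)
    for k, (i, j) in enumerate(stem_pairs):
        for t in range(n_taxa):
            idx = encode_doublet(aln_matrix[t, i], aln_matrix[t, j], n_states,
                                 context=f"row {t}, cols {i + 1}/{j + 1}")
            masks[t, k, list(idx)] = 1
    tips, weights = _compress(masks)
    return EncodedPartition(name=name, spec=spec, tips=tips, weights=weights,
                            n_columns=m, **params)


def empirical_frequencies(ep: EncodedPartition, pseudocount=0.5) -> np.ndarray:
    """State frequencies from the tip masks (ambiguity spread uniformly),
    projected onto the spec's tied groups."""
    mass = ep.tips / ep.tips.sum(axis=2, keepdims=True)
    counts = (mass * ep.weights[None, :, None]).sum(axis=(0, 1)) + pseudocount
    return project_frequencies(ep.spec, counts)


def build_setup_partitions(aln, setup_name: str, *, partitioned=None,
                           loop_params=None, stem_params=None,
                           use_empirical_freqs=True) -> list:
    """Encode a StructuredAlignment for one analysis setup.

    ``setup_name`` is "GTR" (DNA setup: every retained column, stems
    included, as independent nucleotide sites) or a paired-site model name
    (mixed setup: GTR loops + doublet stems).  Parameter dicts may carry
    exch / freqs / alpha / multiplier overrides per partition.
    """
    pdata = partitioned or partition_alignment(aln)
    loop_params = dict(loop_params or {})
    stem_params = dict(stem_params or {})
    parts, overrides = [], []
    if setup_name == "GTR":
        cols = sorted(pdata.loop_columns + pdata.stem_columns)
        if not cols:
            raise SetupError("no columns retained")
        parts.append(encode_loop_partition(aln.matrix[:, cols],
                                           name="all", **loop_params))
        overrides.append(loop_params)
    else:
        spec = get_model(setup_name)
        for tag, cols in pdata.loop_partitions:
            if cols:
                parts.append(encode_loop_partition(
                    aln.matrix[:, cols], name=f"loops:{tag}", **loop_params))
                overrides.append(loop_params)
        parts.append(encode_stem_partition(aln.matrix, pdata.stem_pairs, spec,
                                           **stem_params))
        overrides.append(stem_params)
        if len(parts) == 1:
            log.warning("setup %s has no loop columns; stems only", setup_name)
    if use_empirical_freqs:
        for ep, override in zip(parts, overrides):
            if override.get("freqs") is None:
                ep.freqs = empirical_frequencies(ep)
    return parts


# ---------------------------------------------------------------------------
# pruning

class Traversal:
    """Flattened postorder view of a PhyloTree bound to a taxon order."""

    def __init__(self, tree, taxa):
        self.tree = tree
        taxa = list(taxa)
        tree_taxa = tree.taxa()
        if sorted(taxa) != tree_taxa:
            raise LikelihoodError(
                f"tree taxa {tree_taxa} != data taxa {sorted(taxa)}")
        tip_index = {name: i for i, name in enumerate(taxa)}
        post = tree.postorder()           # children before parents
        self.nodes = []
        index = {}
        internals = [n for n in post if not n.is_leaf]
        n_tips = len(taxa)
        self.n_nodes = n_tips + len(internals)
        slots = [None] * self.n_nodes
        for n in post:
            if n.is_leaf:
                index[id(n)] = tip_index[n.name]
            else:
                index[id(n)] = n_tips + internals.index(n)
            slots[index[id(n)]] = n
        self.nodes = slots
        self.root_idx = index[id(tree.root)]
        self.n_tips = n_tips
        parent = {}
        for n in post:
            for c in n.children:
                parent[id(c)] = id(n)
        self.post_edges = [(index[id(n)], index[parent[id(n)]])
                           for n in post if n is not tree.root]
        self.lengths = np.array(
            [slots[i].length if i != self.root_idx else 0.0
             for i in range(self.n_nodes)])
        self.n_children = np.array([len(n.children) for n in slots])

    def sync_to_tree(self):
        for i, node in enumerate(self.nodes):
            if i != self.root_idx:
                node.length = float(self.lengths[i])


def _partition_loglik(trav: Traversal, ep: EncodedPartition) -> float:
    """Pruning without rescaling (small trees; used to test the scaler)."""
    rm = ep.rate_matrix()
    gam = discretize_gamma(ep.alpha, ep.n_categories)
    n_pat = len(ep.weights)
    cat_logs = np.empty((ep.n_categories, n_pat))
    for ci, r in enumerate(gam.rates):
        ts = trav.lengths * (ep.multiplier * r)
        P = rm.transition_matrices(ts)
        partial = np.ones((trav.n_nodes, n_pat, rm.Q.shape[0]))
        partial[:trav.n_tips] = ep.tips
        for child, parent in trav.post_edges:
            partial[parent] *= partial[child] @ P[child].T
        like = partial[trav.root_idx] @ rm.pi
        cat_logs[ci] = np.log(np.maximum(like, 1e-300))
    site = logsumexp(cat_logs, axis=0) - np.log(ep.n_categories)
    if not np.all(np.isfinite(site)):
        raise LikelihoodError(f"non-finite likelihood in partition {ep.name!r}")
    return float(ep.weights @ site)


def _partition_loglik_scaled(trav: Traversal, ep: EncodedPartition) -> float:
    """Pruning with per-node rescaling (used for everything by default)."""
    rm = ep.rate_matrix()
    gam = discretize_gamma(ep.alpha, ep.n_categories)
    n_pat = len(ep.weights)
    n_states = rm.Q.shape[0]
    cat_logs = np.empty((ep.n_categories, n_pat))
    for ci, r in enumerate(gam.rates):
        ts = trav.lengths * (ep.multiplier * r)
        P = rm.transition_matrices(ts)
        partial = np.ones((trav.n_nodes, n_pat, n_states))
        partial[:trav.n_tips] = ep.tips
        scale = np.zeros(n_pat)
        # number of children not yet folded into each internal node
        remaining = trav.n_children.copy()
        for child, parent in trav.post_edges:
            partial[parent] *= partial[child] @ P[child].T
            remaining[parent] -= 1
            if remaining[parent] == 0 and parent != trav.root_idx:
                m = partial[parent].max(axis=1)
                if np.any(m <= 0):
                    raise LikelihoodError(
                        f"zero partial likelihood in partition {ep.name!r}")
                partial[parent] /= m[:, None]
                scale += np.log(m)
        like = partial[trav.root_idx] @ rm.pi
        if np.any(like <= 0):
            raise LikelihoodError(
                f"zero site likelihood in partition {ep.name!r}")
        cat_logs[ci] = np.log(like) + scale
    m = cat_logs.max(axis=0)
    site = m + np.log(np.exp(cat_logs - m).mean(axis=0))
    if not np.all(np.isfinite(site)):
        raise LikelihoodError(f"non-finite likelihood in partition {ep.name!r}")
    return float(ep.weights @ site)


def loglik(tree, partitions, taxa, *, rescale=True, traversal=None) -> float:
    """Total log-likelihood of ``partitions`` (shared branch lengths)."""
    trav = traversal or Traversal(tree, taxa)
    for ep in partitions:
        if ep.multiplier <= 0:
            raise LikelihoodError(f"rate multiplier <= 0 in {ep.name!r}")
    fn = _partition_loglik_scaled if rescale else _partition_loglik
    return sum(fn(trav, ep) for ep in partitions)


# ---------------------------------------------------------------------------
# information criteria

class AiccError(ValueError):
    pass


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample AIC: -2 logL + 2k + 2k(k+1)/(n-k-1); requires n > k+1.

    No silent AIC fallback: callers with n <= k+1 must decide explicitly.
    """
    if n <= k + 1:
        raise AiccError(
            f"AICc undefined for n={n}, k={k} (need n > k+1); "
            "fall back to AIC explicitly if that is what you want")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# optimization

@dataclass
class FitResult:
    tree: object
    logL: float
    partitions: list
    k: int
    n: int
    aicc: float | None
    converged: bool = True
    rounds: int = 0
    warnings: list = field(default_factory=list)

    def summary(self) -> dict:
        return {"logL": round(self.logL, 6), "k": self.k, "n": self.n,
                "aicc": None if self.aicc is None else round(self.aicc, 6),
                "converged": self.converged,
                "tree": self.tree.to_newick()}


def _pack(parts, flags):
    theta, bounds = [], []
    for ep in parts:
        if flags["exchangeabilities"] and ep.spec.n_exch_classes > 1:
            theta.extend(np.log(ep.exch[1:] / ep.exch[0]))
            bounds.extend([_LOG_RATE_BOUNDS] * (ep.spec.n_exch_classes - 1))
        if flags["alphas"]:
            theta.append(np.log(ep.alpha))
            bounds.append(_LOG_ALPHA_BOUNDS)
    if flags["multipliers"]:
        for ep in parts[1:]:
            theta.append(np.log(ep.multiplier))
            bounds.append(_LOG_RATE_BOUNDS)
    return np.array(theta), bounds


def _unpack(theta, parts, flags):
    pos = 0
    for ep in parts:
        if flags["exchangeabilities"] and ep.spec.n_exch_classes > 1:
            m = ep.spec.n_exch_classes - 1
            ep.exch = np.concatenate([[1.0], np.exp(theta[pos:pos + m])])
            pos += m
        if flags["alphas"]:
            ep.alpha = float(np.exp(theta[pos]))
            pos += 1
    if flags["multipliers"]:
        for ep in parts[1:]:
            ep.multiplier = float(np.exp(theta[pos]))
            pos += 1


def optimize(tree, partitions, taxa, *, branch_lengths=True,
             exchangeabilities=True, alphas=True, multipliers=True,
             tol=1e-3, max_rounds=20, bl_xatol=1e-7) -> FitResult:
    """Alternate branch-length and model-parameter optimization.

    Branch lengths: bracketed 1-D search per branch.  Model parameters:
    bounded L-BFGS-B on log-transformed rates/shapes.  Stops when the
    round-to-round log-likelihood gain falls below ``tol``; the
    log-likelihood never decreases between rounds.
    """
    tree = tree.copy()
    parts = [ep.clone() for ep in partitions]
    flags = {"exchangeabilities": exchangeabilities, "alphas": alphas,
             "multipliers": multipliers and len(parts) > 1}
    trav = Traversal(tree, taxa)

    def current():
        return loglik(None, parts, taxa, traversal=trav)

    cur = current()
    warnings = []
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        prev = cur
        if branch_lengths:
            for e in range(trav.n_nodes):
                if e == trav.root_idx:
                    continue
                t0 = trav.lengths[e]
                f0 = cur

                def neg(t, e=e):
                    trav.lengths[e] = t
                    try:
                        return -current()
                    except LikelihoodError:
                        return 1e12

                res = minimize_scalar(neg, bounds=_BL_BOUNDS, method="bounded",
                                      options={"xatol": bl_xatol})
                if -res.fun > f0:
                    trav.lengths[e] = float(res.x)
                    cur = -res.fun
                else:
                    trav.lengths[e] = t0
        theta0, bounds = _pack(parts, flags)
        if len(theta0):
            def negm(th):
                _unpack(th, parts, flags)
                try:
                    return -current()
                except (LikelihoodError, ValueError):
                    return 1e12

            res = minimize(negm, theta0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 50, "ftol": 1e-9})
            if -res.fun >= cur:
                _unpack(res.x, parts, flags)
                cur = -res.fun
            else:
                _unpack(theta0, parts, flags)
        cur = current()
        if cur < prev - 1e-6:
            raise LikelihoodError(
                f"log-likelihood decreased during optimization "
                f"({prev:.6f} -> {cur:.6f})")
        if cur - prev < tol:
            converged = True
            break
    if not converged:
        warnings.append(f"no convergence after {max_rounds} rounds "
                        f"(last gain {cur - prev:.3g}); best-so-far returned")
        log.warning(warnings[-1])
    trav.sync_to_tree()
    n_edges = trav.n_nodes - 1
    k = count_free_parameters([ep.spec for ep in parts], n_edges)
    n = sum(ep.n_columns for ep in parts)
    try:
        score = aicc(cur, k, n)
    except AiccError as exc:
        score = None
        warnings.append(str(exc))
    return FitResult(tree=tree, logL=cur, partitions=parts, k=k, n=n,
                     aicc=score, converged=converged, rounds=rounds,
                     warnings=warnings)


# ---------------------------------------------------------------------------
# tree search

def distance_matrix(partitions, n_taxa: int) -> np.ndarray:
    """Corrected pairwise distances pooled over partitions (NJ starting
    point).  Only unambiguous sites count; saturation capped."""
    total_d = np.zeros((n_taxa, n_taxa))
    total_w = 0.0
    for ep in partitions:
        resolved = ep.tips.sum(axis=2) == 1          # (taxa, patterns)
        state = ep.tips.argmax(axis=2)
        ns = ep.tips.shape[2]
        pmax = (ns - 1) / ns
        w = ep.weights
        D = np.zeros((n_taxa, n_taxa))
        for a in range(n_taxa):
            for b in range(a + 1, n_taxa):
                ok = resolved[a] & resolved[b]
                tot = float(w[ok].sum())
                if tot == 0:
                    p = 0.0
                else:
                    p = float(w[ok & (state[a] != state[b])].sum()) / tot
                p = min(p, pmax - 1e-3)
                d = -pmax * np.log(1.0 - p / pmax)
                D[a, b] = D[b, a] = d
        total_d += D * ep.n_columns
        total_w += ep.n_columns
    return total_d / max(total_w, 1.0)


def tree_search(partitions, taxa, *, start=None, seed=0, max_nni_rounds=20,
                quick_rounds=2, **opt_kwargs) -> FitResult:
    """ML topology search.

    Four taxa: all three unrooted topologies scored exhaustively.
    Otherwise: NNI hill climbing from a neighbor-joining starting tree
    (or ``start``), accepting the best improving neighbor per sweep.
    Deterministic given the seed and inputs.
    """
    taxa = list(taxa)
    if len(taxa) < 4:
        raise SetupError("tree search needs >= 4 taxa")
    if len(taxa) == 4:
        best = None
        for top in _trees.all_quartets(taxa):
            fit = optimize(top, partitions, taxa, **opt_kwargs)
            if best is None or fit.logL > best.logL:
                best = fit
        return best
    if start is None:
        D = distance_matrix(partitions, len(taxa))
        start = _trees.neighbor_joining(D, taxa)
    best = optimize(start, partitions, taxa, **opt_kwargs)
    start_logL = best.logL
    # NNI sweeps re-optimize branch lengths only, reusing the fitted model
    # parameters; the winner gets one final full optimization.
    fitted = best.partitions
    cur_tree, cur_logL = best.tree, best.logL
    accepted = False
    for _ in range(max_nni_rounds):
        cand = None
        for nb in cur_tree.nni_neighbors():
            try:
                fit = optimize(nb, fitted, taxa, exchangeabilities=False,
                               alphas=False, multipliers=False,
                               max_rounds=quick_rounds, tol=1e-2,
                               bl_xatol=1e-4)
            except LikelihoodError:
                continue
            if fit.logL > cur_logL + 1e-6 and (cand is None or fit.logL > cand.logL):
                cand = fit
        if cand is None:
            break
        cur_tree, cur_logL = cand.tree, cand.logL
        accepted = True
    if accepted:
        best = optimize(cur_tree, fitted, taxa, **opt_kwargs)
    if best.logL < start_logL - 1e-6:  # pragma: no cover - hill-climb invariant
        raise LikelihoodError("search returned worse tree than start")
    return best
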