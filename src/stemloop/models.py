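"""Substitution models for stem/loop-partitioned rRNA analysis.

Loops (unpaired columns) evolve as independent nucleotide sites under GTR;
stems (paired columns) evolve as doublets under one of 13 paired-site RNA
models on 6, 7 or 16 states.  The model families differ along two axes:

* step class -- "one-step" models allow compensatory double substitutions
  directly (e.g. AU <-> GC has a nonzero rate), "two-step" models set every
  double substitution to rate zero so a pair change must pass through an
  intermediate (mismatch or GU-type) state;
* mismatch policy -- 6-state models ignore non-canonical doublets (they are
  treated as missing data), 7-state models lump all mismatches into a single
  MM state, 16-state models give every ordered doublet its own state.

Within each family the lettered variants tie parameters to differing
degrees, from fully general reversible (the "A" variants, RNA16, RNA16A)
down to a single exchangeability class (the "D"/"F" variants, RNA16B).
All models are reversible: Q_ij = s_ij * pi_j with symmetric
exchangeabilities s, calibrated so the stationary mean substitution rate
is one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist


class ModelError(ValueError):
    """Invalid model specification or parameterization."""


NUCLEOTIDES = "ACGU"
#: canonical (bonding) doublet states in the conventional 6-state order
PAIR6 = ("AU", "GU", "GC", "UA", "UG", "CG")
STATES7 = PAIR6 + ("MM",)
#: ordered nucleotide pairs; the 16-state space
STATES16 = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
CANONICAL_PAIRS = frozenset(PAIR6)
MISMATCH_DOUBLETS = tuple(s for s in STATES16 if s not in CANONICAL_PAIRS)

ONE_STEP = "one_step"
TWO_STEP = "two_step"

# transition categories between doublet states
_SINGLE = "single"          # one member of the pair changes
_WC_DOUBLE = "wc_double"    # both change, canonical pair -> canonical pair
_OTHER_DOUBLE = "other_double"
_PAIR_MM = "pair_mm"        # canonical pair <-> lumped mismatch state (7-state)


def _doublet_category(s: str, t: str) -> str:
    if s == "MM" or t == "MM":
        return _PAIR_MM
    diff = (s[0] != t[0]) + (s[1] != t[1])
    if diff == 1:
        return _SINGLE
    if s in CANONICAL_PAIRS and t in CANONICAL_PAIRS:
        return _WC_DOUBLE
    return _OTHER_DOUBLE


@dataclass(frozen=True)
class ModelSpec:
    """A named substitution model with its structural constraints.

    ``exch_classes`` maps each unordered state pair (i<j) to a tied
    exchangeability class id, or -1 for a structural zero (forbidden
    transition).  ``class_categories`` records, per class id, which
    transition category its members belong to (used for default
    parameter values and reporting).  ``freq_groups`` maps each state to
    a tied-frequency group.
    """

    name: str
    states: tuple
    step_class: str | None
    mismatch_policy: str
    exch_classes: tuple          # flattened dict: ((i, j, class_id), ...)
    class_categories: tuple      # per class id: category name
    freq_groups: tuple           # per state: group id
    class_source: str = "literature"

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_exch_classes(self) -> int:
        return len(self.class_categories)

    @property
    def free_exchangeabilities(self) -> int:
        # one class is absorbed by the overall rate calibration
        return self.n_exch_classes - 1

    @property
    def free_frequencies(self) -> int:
        return len(set(self.freq_groups)) - 1

    def class_matrix(self) -> np.ndarray:
        """(n, n) int matrix of class ids, -1 where the rate is structurally zero."""
        n = self.n_states
        m = np.full((n, n), -1, dtype=int)
        for i, j, c in self.exch_classes:
            m[i, j] = m[j, i] = c
        return m

    def forbidden_pairs(self):
        """Unordered state pairs whose exchangeability is structurally zero."""
        m = self.class_matrix()
        return [(i, j) for i, j in combinations(range(self.n_states), 2) if m[i, j] < 0]


def _assign_classes(states, allowed_category, tying):
    """Build (exch_classes, class_categories) for a doublet state space."""
    entries = []
    categories = []
    by_cat_index: dict = {}
    cat_class: dict = {}
    for i, j in combinations(range(len(states)), 2):
        cat = _doublet_category(states[i], states[j])
        if not allowed_category(cat):
            continue
        if tying == "general":
            cid = len(categories)
            categories.append(cat)
        elif tying == "classes":
            if cat not in cat_class:
                cat_class[cat] = len(categories)
                categories.append(cat)
            cid = cat_class[cat]
        elif tying == "equal":
            if not categories:
                categories.append("any")
            cid = 0
        else:  # pragma: no cover
            raise ModelError(f"unknown tying {tying!r}")
        by_cat_index.setdefault(cat, 0)
        by_cat_index[cat] += 1
        entries.append((i, j, cid))
    return tuple(entries), tuple(categories)


def _freq_groups_rc(states):
    """Tie frequencies across reverse-complement partners (pi_AU = pi_UA, ...)."""
    groups = {}
    out = []
    for s in states:
        key = min(s, s[::-1]) if s != "MM" else "MM"
        if key not in groups:
            groups[key] = len(groups)
        out.append(groups[key])
    return tuple(out)


def _doublet_spec(name, states, step_class, mismatch_policy, tying, *,
                  rc_tied_freqs=False, wc_doubles_only=False,
                  class_source="literature") -> ModelSpec:
    def allowed(cat):
        if cat in (_SINGLE, _PAIR_MM):
            return True
        if step_class == TWO_STEP:
            return False
        if wc_doubles_only:
            return cat == _WC_DOUBLE
        return True

    exch, cats = _assign_classes(states, allowed, tying)
    freq_groups = _freq_groups_rc(states) if rc_tied_freqs else tuple(range(len(states)))
    return ModelSpec(name=name, states=tuple(states), step_class=step_class,
                     mismatch_policy=mismatch_policy, exch_classes=exch,
                     class_categories=cats, freq_groups=freq_groups,
                     class_source=class_source)


def _gtr_spec() -> ModelSpec:
    states = tuple(NUCLEOTIDES)
    entries = []
    for cid, (i, j) in enumerate(combinations(range(4), 2)):
        entries.append((i, j, cid))
    return ModelSpec(name="GTR", states=states, step_class=None,
                     mismatch_policy="n/a", exch_classes=tuple(entries),
                     class_categories=tuple("nt" for _ in entries),
                     freq_groups=(0, 1, 2, 3))


def _make_registry():
    reg = {"GTR": _gtr_spec()}
    six = {"A": "general", "B": "classes", "C": "classes", "D": "equal"}
    for v, tying in six.items():
        reg[f"RNA6{v}"] = _doublet_spec(
            f"RNA6{v}", PAIR6, ONE_STEP, "ignore", tying,
            rc_tied_freqs=(v == "C"))
    seven = {
        "A": (ONE_STEP, "general", "literature"),
        "B": (ONE_STEP, "classes", "literature"),
        "C": (TWO_STEP, "general", "literature"),
        "D": (ONE_STEP, "equal", "literature"),
        "E": (TWO_STEP, "classes", "implementation_default"),
        "F": (TWO_STEP, "equal", "literature"),
    }
    for v, (step, tying, src) in seven.items():
        reg[f"RNA7{v}"] = _doublet_spec(
            f"RNA7{v}", STATES7, step, "lump", tying, class_source=src)
    reg["RNA16"] = _doublet_spec("RNA16", STATES16, TWO_STEP, "distinct", "general")
    reg["RNA16A"] = _doublet_spec("RNA16A", STATES16, ONE_STEP, "distinct",
                                  "general", wc_doubles_only=True)
    reg["RNA16B"] = _doublet_spec("RNA16B", STATES16, TWO_STEP, "distinct", "equal")
    return reg


REGISTRY = _make_registry()
#: the 13 paired-site models used in mixed RNA/DNA setups
MIXED_MODELS = tuple(n for n in REGISTRY if n != "GTR")
#: the 14 analysis setups: one DNA-only plus the 13 mixed setups
SETUP_NAMES = ("GTR",) + MIXED_MODELS


def get_model(name: str) -> ModelSpec:
    try:
        return REGISTRY[name]
    except KeyError:
        raise ModelError(f"unknown model {name!r}; known: {sorted(REGISTRY)}") from None


# ---------------------------------------------------------------------------
# default parameter values

_DEFAULT_CAT_RATE = {_SINGLE: 2.0, _WC_DOUBLE: 1.0, _OTHER_DOUBLE: 0.12,
                     _PAIR_MM: 0.45, "any": 1.0, "nt": 1.0}
# deterministic spread so fully general models are genuinely heterogeneous
_SPREAD = (0.5, 1.0, 2.2)

_DEFAULT_GTR_EXCH = np.array([1.0, 4.0, 0.7, 0.9, 4.5, 1.0])  # AC AG AU CG CU GU
_DEFAULT_FREQS4 = np.array([0.26, 0.22, 0.28, 0.24])
_DEFAULT_FREQS6 = np.array([0.17, 0.05, 0.33, 0.15, 0.06, 0.24])


def default_parameters(spec: ModelSpec):
    """Deterministic, heterogeneous default (exchangeabilities, frequencies)."""
    if spec.name == "GTR":
        return _DEFAULT_GTR_EXCH.copy(), _DEFAULT_FREQS4.copy()
    exch = np.empty(spec.n_exch_classes)
    seen: dict = {}
    for cid, cat in enumerate(spec.class_categories):
        k = seen.get(cat, 0)
        seen[cat] = k + 1
        spread = _SPREAD[k % 3] if spec.n_exch_classes > len(set(spec.class_categories)) else 1.0
        exch[cid] = _DEFAULT_CAT_RATE[cat] * spread
    n = spec.n_states
    if n == 6:
        freqs = _DEFAULT_FREQS6.copy()
    elif n == 7:
        freqs = np.concatenate([_DEFAULT_FREQS6 * 0.94, [0.06]])
    else:
        freqs = np.full(16, 0.01)
        for s, f in zip(PAIR6, _DEFAULT_FREQS6 * 0.90):
            freqs[STATES16.index(s)] = f
    freqs = project_frequencies(spec, freqs)
    return exch, freqs


def project_frequencies(spec: ModelSpec, freqs) -> np.ndarray:
    """Average frequencies within tied groups and renormalize."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (spec.n_states,):
        raise ModelError(f"{spec.name}: expected {spec.n_states} frequencies, "
                         f"got {freqs.shape}")
    groups = np.asarray(spec.freq_groups)
    out = freqs.copy()
    for g in np.unique(groups):
        mask = groups == g
        out[mask] = freqs[mask].mean()
    total = out.sum()
    if total <= 0:
        raise ModelError(f"{spec.name}: frequencies sum to {total}")
    return out / total


# ---------------------------------------------------------------------------
# rate matrices

@dataclass
class RateMatrix:
    """Calibrated reversible generator: rows sum to 0, mean rate 1."""

    Q: np.ndarray
    pi: np.ndarray
    states: tuple
    _decomp: tuple = field(default=None, repr=False, compare=False)

    def decomposition(self):
        """Eigendecomposition Q = A diag(lam) B via the symmetric similarity
        transform (valid for reversible Q with pi > 0)."""
        if self._decomp is None:
            d = np.sqrt(self.pi)
            S = (self.Q * d[:, None]) / d[None, :]
            S = 0.5 * (S + S.T)
            lam, U = np.linalg.eigh(S)
            A = U / d[:, None]
            B = U.T * d[None, :]
            object.__setattr__(self, "_decomp", (A, lam, B))
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        A, lam, B = self.decomposition()
        P = (A * np.exp(lam * t)) @ B
        np.clip(P, 0.0, None, out=P)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of times; shape (len(ts), n, n)."""
        A, lam, B = self.decomposition()
        E = np.exp(np.multiply.outer(np.asarray(ts, dtype=float), lam))
        P = np.einsum("ik,ek,kj->eij", A, E, B)
        np.clip(P, 0.0, None, out=P)
        return P


def build_rate_matrix(spec: ModelSpec, exch=None, freqs=None) -> RateMatrix:
    """Construct the calibrated reversible generator for ``spec``.

    ``exch`` gives one rate per exchangeability class (the overall scale is
    irrelevant: the matrix is recalibrated to mean rate 1); ``freqs`` the
    stationary frequencies (projected onto the spec's tied groups).
    """
    if exch is None or freqs is None:
        d_exch, d_freqs = default_parameters(spec)
        exch = d_exch if exch is None else exch
        freqs = d_freqs if freqs is None else freqs
    exch = np.asarray(exch, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if exch.shape != (spec.n_exch_classes,):
        raise ModelError(f"{spec.name}: expected {spec.n_exch_classes} "
                         f"exchangeability classes, got {exch.shape}")
    if np.any(exch <= 0) or not np.all(np.isfinite(exch)):
        raise ModelError(f"{spec.name}: exchangeabilities must be finite and > 0")
    pi = project_frequencies(spec, freqs)
    if np.any(pi <= 0):
        zero = [spec.states[i] for i in np.where(pi <= 0)[0]]
        raise ModelError(f"{spec.name}: zero frequency for reachable state(s) {zero}")
    n = spec.n_states
    S = np.zeros((n, n))
    for i, j, cid in spec.exch_classes:
        S[i, j] = S[j, i] = exch[cid]
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ModelError(f"{spec.name}: degenerate generator (mean rate {mu})")
    return RateMatrix(Q=Q / mu, pi=pi, states=spec.states)


# ---------------------------------------------------------------------------
# discrete gamma rate variation

@dataclass(frozen=True)
class GammaRates:
    """Equal-probability discrete approximation of Gamma(alpha, alpha) rates."""

    alpha: float
    n_categories: int
    rates: tuple
    probs: tuple


@lru_cache(maxsize=512)
def discretize_gamma(alpha: float, k: int = 4) -> GammaRates:
    """Mean-one discrete gamma: k equal-probability categories, each
    represented by its conditional (quartile) mean."""
    if not (alpha > 0):
        raise ModelError(f"gamma shape must be > 0, got {alpha}")
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X; X <= x] for X ~ Gamma(a, rate=a) is gammainc(a+1, a*x)
    cum = gammainc(alpha + 1.0, alpha * edges)
    cum[0], cum[-1] = 0.0, 1.0
    rates = k * np.diff(cum)
    rates = rates / rates.mean()
    return GammaRates(alpha=float(alpha), n_categories=k,
                      rates=tuple(rates), probs=tuple(np.full(k, 1.0 / k)))


# ---------------------------------------------------------------------------
# parameter accounting

def count_free_parameters(partition_specs, n_branches: int) -> int:
    """Free parameters of a partitioned setup with shared branch lengths.

    Per partition: free exchangeabilities + free frequencies + one gamma
    shape.  Shared: branch lengths, plus one free rate multiplier per
    partition beyond the first (the first is fixed to 1).
    """
    specs = list(partition_specs)
    k = n_branches + max(0, len(specs) - 1)
    for spec in specs:
        k += spec.free_exchangeabilities + spec.free_frequencies + 1
    return k
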