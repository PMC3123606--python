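"""Tree comparison: Robinson-Foulds distances and benchmark-clade checks.

Trees are unrooted throughout; monophyly is always evaluated relative to a
declared outgroup.  Polytomies are allowed -- the RF distance uses whatever
non-trivial bipartitions exist, without arbitrary resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

from .trees import PhyloTree, TreeError


@dataclass(frozen=True)
class ComparisonResult:
    rf: int
    rf_normalized: float
    n_shared: int


@dataclass(frozen=True)
class BenchmarkClade:
    name: str
    taxa: frozenset
    expected: str = "monophyletic"


@dataclass(frozen=True)
class MonophylyResult:
    monophyletic: bool
    smallest_containing: frozenset | None = None


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> ComparisonResult:
    """Symmetric-difference RF distance on the shared leaf set, normalized
    by 2(n-3), the maximum for binary unrooted trees on n leaves."""
    shared = set(t1.taxa()) & set(t2.taxa())
    n = len(shared)
    if n < 4:
        raise TreeError(f"RF needs >= 4 shared leaves, got {n}")
    r1 = t1 if len(t1.taxa()) == n else t1.restrict(shared)
    r2 = t2 if len(t2.taxa()) == n else t2.restrict(shared)
    d = len(r1.bipartitions() ^ r2.bipartitions())
    return ComparisonResult(rf=d, rf_normalized=d / (2 * (n - 3)), n_shared=n)


def check_monophyly(tree: PhyloTree, clade, outgroup) -> MonophylyResult:
    """Is ``clade`` one side of a bipartition with the outgroup entirely on
    the other side?  When false, the smallest clade (rooted on the
    outgroup) containing the set is returned as a diagnostic."""
    clade = frozenset(clade)
    outgroup = frozenset(outgroup)
    leaves = frozenset(tree.taxa())
    if clade & outgroup:
        raise TreeError(f"clade and outgroup overlap: {sorted(clade & outgroup)}")
    missing = (clade | outgroup) - leaves
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    ingroup = leaves - outgroup
    if len(clade) <= 1 or clade == ingroup:
        return MonophylyResult(True)
    for side, comp in tree.bipartition_sides():
        if side == clade and outgroup <= comp:
            return MonophylyResult(True)
        if comp == clade and outgroup <= side:
            return MonophylyResult(True)
    candidates = [s for s, c in tree.bipartition_sides()
                  if clade <= s and not (s & outgroup)]
    candidates += [c for s, c in tree.bipartition_sides()
                   if clade <= c and not (c & outgroup)]
    smallest = min(candidates, key=len) if candidates else ingroup
    return MonophylyResult(False, smallest_containing=frozenset(smallest))


def benchmark_matrix(fits: dict, clades, outgroup) -> pd.DataFrame:
    """Per-setup benchmark verdicts: one row per setup, one column per
    clade, plus 'all_pass' (every expected clade monophyletic)."""
    rows = []
    for setup, fit in fits.items():
        tree = fit.tree if hasattr(fit, "tree") else fit
        row = {"setup": setup}
        ok = True
        for clade in clades:
            res = check_monophyly(tree, clade.taxa, outgroup)
            row[clade.name] = res.monophyletic
            ok = ok and res.monophyletic
        row["all_pass"] = ok
        rows.append(row)
    return pd.DataFrame(rows).set_index("setup")


def load_clade_config(path):
    """YAML clade config: {outgroup: [taxa], clades: {name: [taxa]}}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    outgroup = frozenset(cfg.get("outgroup", []))
    clades = [BenchmarkClade(name=k, taxa=frozenset(v))
              for k, v in (cfg.get("clades") or {}).items()]
    return clades, outgroup
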