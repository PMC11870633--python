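"""Rank-correlation evaluation of distance estimators against tree distance.

The benchmark premise: if an estimator measures evolutionary distance
well, its pairwise values should be monotonically related to the
patristic distances on the true species tree.  Agreement is quantified
with Spearman's rank correlation; because the interesting p-values are
astronomically small, the two-sided p is evaluated in log space via the
t approximation t = rho * sqrt((n-2)/(1-rho^2)) and reported as log10(p).

``merge_ranks`` implements the bi-k trick: two distance matrices (for
example Jaccard at k=10 and k=19) are each rank-transformed, the ranks
averaged per pair, and the averaged ranks used as a new distance —
combining complementary signal from two k-mer scales.

``run_benchmark`` drives full scenario grids: simulate genomes, run a set
of estimators, evaluate each against the truth tree, and aggregate
medians across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from . import kmers as km
from . import align as al
from .matrix import DistanceMatrix, iter_pairs
from .simulate import HomologyMap, SimConfig, SimGenome, evolve, patristic_matrix, sample_species_tree

__all__ = [
    "EvalResult",
    "spearman_log",
    "evaluate_tool",
    "merge_ranks",
    "estimator_matrix",
    "anim_matrices",
    "BenchmarkGrid",
    "run_benchmark",
    "summarize_benchmark",
]

LOG10 = np.log(10.0)


def spearman_log(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Spearman rho and log10 of the two-sided p-value.

    rho is the Pearson correlation of average-tie ranks; the p-value uses
    the t approximation with the survival function evaluated in log space
    so it never underflows for |rho| < 1.  Constant input yields
    (nan, nan).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise DataError(f"need at least 4 observations, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, float("-inf")
    t = abs(rho) * np.sqrt((n - 2) / (1.0 - rho * rho))
    log_p = np.log(2.0) + _t_logsf(t, n - 2)
    return rho, float(log_p / LOG10)


def _t_logsf(t: float, df: int) -> float:
    """log of the t survival function, robust for extreme t.

    scipy's logsf underflows to -inf once sf drops below the smallest
    double; beyond that point the power-law tail expansion
    sf(t) ~ c(df) * df^{(df+1)/2} * t^{-df} / df * (1 - df(df+1)/(2(df+2)t^2))
    takes over, so the result stays finite for every |rho| < 1.
    """
    lp = float(stats.t.logsf(t, df))
    if np.isfinite(lp):
        return lp
    from scipy.special import gammaln

    log_c = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
    lead = log_c + (df + 1) / 2 * np.log(df) - np.log(df) - df * np.log(t)
    correction = -df * (df + 1) / (2.0 * (df + 2) * t * t)
    return lead + np.log1p(correction) if correction > -1 else lead


@dataclass
class EvalResult:
    """Spearman agreement of one estimator with the truth tree distance.

    ``rho`` is on the internal distance convention (similarities are
    negated first, so a good estimator has rho > 0); ``rho_signed`` is
    the correlation of the raw estimator values with tree distance (for
    a similarity such as ANI a good estimator has rho_signed < 0).
    """

    rho: float
    rho_signed: float
    log10_p: float
    n_pairs: int
    n_undefined: int
    method: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)


def evaluate_tool(
    dm: DistanceMatrix,
    truth: DistanceMatrix,
    drop_undefined: bool = False,
) -> EvalResult:
    """Correlate an estimator's pairwise values with true tree distances.

    Undefined pairs (e.g. ANI with no surviving alignment) are by default
    included as ties at the maximal distance, mirroring tools that report
    an ANI of zero for unalignable pairs; ``drop_undefined`` excludes
    them instead.
    """
    if truth.kind != "distance":
        raise DataError("truth matrix must have kind='distance'")
    if list(dm.labels) != list(truth.labels):
        if set(dm.labels) != set(truth.labels):
            raise DataError("label sets differ between estimate and truth")
        order = [dm.labels.index(lab) for lab in truth.labels]
        idx = np.array(order)
        dm = DistanceMatrix(
            labels=list(truth.labels),
            values=dm.values[np.ix_(idx, idx)],
            kind=dm.kind,
            method=dm.method,
            defined=dm.defined[np.ix_(idx, idx)],
        )
    vals, defined = dm.condensed()
    tvals, _ = truth.condensed()
    n_undef = int((~defined).sum())
    if drop_undefined:
        vals, tvals = vals[defined], tvals[defined]
    else:
        vals = vals.copy()
        if dm.kind == "similarity":
            vals[~defined] = 0.0  # similarity zero = maximal distance
        else:
            vals[~defined] = vals[defined].max() if defined.any() else 1.0
    if vals.size < 4:
        raise DataError("fewer than 4 usable pairs")
    rho_signed, log10_p = spearman_log(vals, tvals)
    if np.isnan(rho_signed):
        rho = float("nan")
    else:
        rho = -rho_signed if dm.kind == "similarity" else rho_signed
    return EvalResult(
        rho=rho,
        rho_signed=rho_signed,
        log10_p=log10_p,
        n_pairs=int(vals.size),
        n_undefined=n_undef,
        method=dict(dm.method),
    )


def merge_ranks(d1: DistanceMatrix, d2: DistanceMatrix) -> DistanceMatrix:
    """Average the per-pair ranks of two matrices into a new distance.

    Each matrix's pair values are rank-transformed (average ranks for
    ties, similarities ranked descending so that rank increases with
    distance), the two ranks averaged per pair, and the averages returned
    as the merged distance. The result is invariant to any strictly
    monotone transform of either input.
    """
    if list(d1.labels) != list(d2.labels):
        raise DataError("label sets differ between matrices")
    if d1.kind != d2.kind:
        raise DataError("matrices must share kind")
    v1, def1 = d1.condensed()
    v2, def2 = d2.condensed()

    def ranks(v: np.ndarray, defined: np.ndarray, kind: str) -> np.ndarray:
        v = v.copy()
        if kind == "similarity":
            v[~defined] = 0.0
            v = -v
        else:
            v[~defined] = v[defined].max() + 1.0 if defined.any() else 1.0
        return stats.rankdata(v)

    merged = 0.5 * (ranks(v1, def1, d1.kind) + ranks(v2, def2, d2.kind))
    n = d1.n
    values = np.zeros((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    values[iu] = merged
    values = values + values.T
    return DistanceMatrix(
        labels=list(d1.labels),
        values=values,
        kind="distance",
        method={"method": "merged_ranks",
                "inputs": [d1.method, d2.method]},
    )


# ---------------------------------------------------------------------------
# estimator registry


def _kmer_sets(genomes: dict[str, SimGenome], k: int, hash_seed: int,
               regions: dict[str, list[tuple[int, int]]] | None = None):
    out = {}
    for label, g in genomes.items():
        seq = g.sequence if isinstance(g, SimGenome) else g
        if regions is None:
            out[label] = km.canonical_kmers(seq, k, hash_seed, label)
        else:
            out[label] = km.region_restricted_kmers(
                seq, regions.get(label, []), k, hash_seed, label
            )
    return out


def estimator_matrix(
    genomes: dict[str, SimGenome],
    spec: dict,
    homology: HomologyMap | None = None,
    hash_seed: int = km.DEFAULT_HASH_SEED,
) -> DistanceMatrix:
    """Run one estimator over all genome pairs.

    ``spec`` selects the method and its parameters:

    - ``{"method": "jaccard", "k": 15}`` exact Jaccard (similarity)
    - ``{"method": "mash", "k": 21, "s": 1000}`` Mash index (similarity)
    - ``{"method": "jaccard_vertical", "k": 15}`` Jaccard restricted to
      vertically inherited genes (requires ``homology``)
    - ``{"method": "gc"}`` GC-content distance
    - ``{"method": "anim", "min_len": 20, "anchor_mode": "mum",
         "filter_1to1": True, "af_weight": False}`` (similarity)
    - ``{"method": "anib", ...}`` / ``{"method": "orthoani", ...}``
    """
    labels = sorted(genomes)
    method = spec.get("method")
    params = {k_: v for k_, v in spec.items() if k_ != "method"}
    seqs = {
        lab: (g.sequence if isinstance(g, SimGenome) else g)
        for lab, g in genomes.items()
    }

    if method in ("jaccard", "jaccard_vertical"):
        k = params.get("k", 21)
        regions = None
        if method == "jaccard_vertical":
            if homology is None:
                raise ConfigError("jaccard_vertical requires a homology map")
            regions = {
                lab: genomes[lab].gene_intervals({"vertical"}) for lab in labels
            }
        sets = _kmer_sets(genomes, k, hash_seed, regions)
        func = lambda i, j: km.jaccard(sets[labels[i]], sets[labels[j]])
        kind = "similarity"
    elif method == "mash":
        k = params.get("k", 21)
        s = params.get("s", 1000)
        mode = params.get("mode", "merged")
        sets = _kmer_sets(genomes, k, hash_seed)
        sketches = {lab: km.minhash_sketch(sets[lab], s) for lab in labels}

        def func(i, j):
            jv = km.sketched_jaccard(sketches[labels[i]], sketches[labels[j]], mode)
            return None if np.isnan(jv) else km.mash_index(jv, k)

        kind = "similarity"
    elif method == "gc":
        func = lambda i, j: km.gc_distance(seqs[labels[i]], seqs[labels[j]])
        kind = "distance"
    elif method == "anim":
        af_weight = params.pop("af_weight", False)

        def func(i, j):
            r = al.anim(seqs[labels[i]], seqs[labels[j]], **params)
            if not r.defined:
                return None
            return al.af_weighted(r) if af_weight else r.ani

        kind = "similarity"
    elif method in ("anib", "orthoani"):
        fn = al.anib if method == "anib" else al.orthoani
        af_weight = params.pop("af_weight", False)

        def func(i, j):
            r = fn(seqs[labels[i]], seqs[labels[j]], **params)
            if not r.defined:
                return None
            return al.af_weighted(r) if af_weight else r.ani

        kind = "similarity"
    else:
        raise ConfigError(f"unknown estimator method: {method!r}")

    return DistanceMatrix.from_pairs(labels, func, kind=kind, method=dict(spec))


def anim_matrices(
    genomes: dict[str, SimGenome],
    min_len: int = 20,
    anchor_mode: str = "mum",
    filter_1to1: bool = True,
) -> tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix]:
    """One ANIm pass per pair, returning (ANI, ANI*AF, AF) matrices.

    The AF-weighted similarity is a post-processing of the same
    alignment, so computing the three matrices together halves the cost
    relative to separate :func:`estimator_matrix` calls.
    """
    labels = sorted(genomes)
    seqs = {
        lab: (g.sequence if isinstance(g, SimGenome) else g)
        for lab, g in genomes.items()
    }
    n = len(labels)
    base = {"min_len": min_len, "anchor_mode": anchor_mode, "filter_1to1": filter_1to1}
    vals_ani = np.zeros((n, n))
    vals_af = np.zeros((n, n))
    vals_frac = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i, j in iter_pairs(labels):
        r = al.anim(seqs[labels[i]], seqs[labels[j]], **base)
        frac = 0.5 * (r.af_query + r.af_ref)
        vals_frac[i, j] = vals_frac[j, i] = frac
        if r.defined:
            vals_ani[i, j] = vals_ani[j, i] = r.ani
            vals_af[i, j] = vals_af[j, i] = r.ani * frac
        else:
            defined[i, j] = defined[j, i] = False
    for v in (vals_ani, vals_af, vals_frac):
        np.fill_diagonal(v, max(1.0, v.max()))
    mk = lambda v, name, dflt: DistanceMatrix(
        labels=labels, values=v, kind="similarity",
        method={"method": name, **base}, defined=dflt,
    )
    return (
        mk(vals_ani, "anim", defined),
        mk(vals_af, "anim_af", defined),
        mk(vals_frac, "anim_frac", np.ones((n, n), dtype=bool)),
    )


# ---------------------------------------------------------------------------
# scenario grids


@dataclass
class BenchmarkGrid:
    """A grid of simulation scenarios crossed with estimators."""

    estimators: list[dict]
    mutation_rates: list[float] = field(default_factory=lambda: [50.0])
    dup_rates: list[float] = field(default_factory=lambda: [0.0])
    lgt_rates: list[float] = field(default_factory=lambda: [0.0])
    n_replicates: int = 5
    base_seed: int = 0
    base_config: SimConfig = field(default_factory=SimConfig)
    drop_undefined: bool = False

    def validate(self) -> None:
        if not self.estimators:
            raise ConfigError("benchmark grid needs at least one estimator")
        if not (self.mutation_rates and self.dup_rates and self.lgt_rates):
            raise ConfigError("benchmark grid axes must be non-empty")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


def _cell_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    return (base_seed * 1_000_003 + cell_index * 10_007 + replicate * 101 + 13) % (
        2**31
    )


def run_benchmark(grid: BenchmarkGrid) -> pd.DataFrame:
    """Simulate every scenario cell and evaluate every estimator on it.

    Returns a tidy frame with one row per (scenario, replicate,
    estimator); aggregate with :func:`summarize_benchmark`.
    """
    grid.validate()
    rows = []
    cell_index = 0
    from dataclasses import replace as dc_replace

    for mut in grid.mutation_rates:
        for dup in grid.dup_rates:
            for lgt in grid.lgt_rates:
                cell_index += 1
                for rep in range(grid.n_replicates):
                    seed = _cell_seed(grid.base_seed, cell_index, rep)
                    cfg = dc_replace(
                        grid.base_config,
                        mutation_rate=mut,
                        dup_rate=dup,
                        lgt_rate=lgt,
                        seed=seed,
                    )
                    tree = sample_species_tree(cfg)
                    genomes, homology = evolve(tree, cfg)
                    truth = patristic_matrix(tree)
                    for est in grid.estimators:
                        dm = estimator_matrix(genomes, est, homology=homology)
                        res = evaluate_tool(
                            dm, truth, drop_undefined=grid.drop_undefined
                        )
                        rows.append(
                            {
                                "mutation_rate": mut,
                                "dup_rate": dup,
                                "lgt_rate": lgt,
                                "estimator": _estimator_label(est),
                                "rho": res.rho,
                                "rho_signed": res.rho_signed,
                                "log10_p": res.log10_p,
                                "n_pairs": res.n_pairs,
                                "n_undefined": res.n_undefined,
                                "replicate": rep,
                                "seed": seed,
                            }
                        )
    return pd.DataFrame(rows)


def _estimator_label(spec: dict) -> str:
    method = spec.get("method", "?")
    extras = [f"{k}={v}" for k, v in sorted(spec.items()) if k != "method"]
    return method if not extras else f"{method}({','.join(extras)})"


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Median and mean rho / log10 p per scenario cell and estimator."""
    keys = ["mutation_rate", "dup_rate", "lgt_rate", "estimator"]
    agg = df.groupby(keys, as_index=False).agg(
        rho_median=("rho", "median"),
        rho_mean=("rho", "mean"),
        log10_p_median=("log10_p", "median"),
        log10_p_mean=("log10_p", "mean"),
        n_replicates=("replicate", "count"),
        n_undefined_median=("n_undefined", "median"),
    )
    return agg
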