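"""The feature-selection funnel.

Normalize the cohort table, keep the features whose means differ between the
propensity group and controls under a lenient Welch test (p < 0.3), connect
pairs of retained features whose absolute Pearson correlation does NOT exceed
0.3, enumerate maximal cliques of at least 8 mutually weakly-correlated
features, and sample candidate combinations from them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureTable, Group

log = logging.getLogger(__name__)


@dataclass
class FeatureCombination:
    """A candidate feature set originating from one maximal clique."""

    features: tuple[str, ...]
    origin_clique: int

    def __len__(self) -> int:
        return len(self.features)


def standard_normalize(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Center each column to mean 0 and scale to population sd 1.

    Zero-variance columns are left centered (all zeros) and returned as the
    flagged list. NaN cells are imputed with the column mean beforehand (a
    subject can lack e.g. nocturnal features on a sleepless recording).
    """
    df = table.frame.copy()
    n_imputed = int(df.isna().sum().sum())
    if n_imputed:
        log.info("imputing %d missing feature cells with column means", n_imputed)
        df = df.fillna(df.mean())
    mean = df.mean()
    sd = df.std(ddof=0)
    flagged = list(df.columns[(sd == 0) | sd.isna()])
    sd = sd.replace(0, 1.0).fillna(1.0)
    out = (df - mean) / sd
    out = out.fillna(0.0)  # all-NaN columns
    return FeatureTable(out, table.labels.copy(), table.registry_version), flagged


def welch_filter(table: FeatureTable, positive: Group, control: Group = Group.C,
                 alpha: float = 0.3) -> list[str]:
    """Features with two-sided Welch-test p < alpha between the two groups.

    Degenerate features (zero variance in both classes) get p = NaN from the
    test and are dropped with a log entry.
    """
    a = table.frame[table.labels == positive]
    b = table.frame[table.labels == control]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both classes need at least 2 subjects")
    res = stats.ttest_ind(a.values, b.values, axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue)
    kept = [name for name, p in zip(table.feature_names, pvals)
            if np.isfinite(p) and p < alpha]
    n_degenerate = int(np.sum(~np.isfinite(pvals)))
    if n_degenerate:
        log.info("welch filter: %d degenerate features dropped", n_degenerate)
    log.info("welch filter (alpha=%.2f, %s vs %s): kept %d of %d features",
             alpha, positive.value, control.value, len(kept), len(table.feature_names))
    return kept


def build_low_correlation_graph(table: FeatureTable, threshold: float = 0.3
                                ) -> nx.Graph:
    """Graph whose edges join feature pairs with |Pearson r| <= threshold
    (edges whose weight *exceeds* the threshold are deleted)."""
    corr = table.frame.corr(method="pearson").abs()
    g = nx.Graph()
    names = list(table.frame.columns)
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r <= threshold:
                g.add_edge(a, b, weight=float(r))
    log.info("correlation graph: %d nodes, %d edges at |r| <= %.2f",
             g.number_of_nodes(), g.number_of_edges(), threshold)
    return g


def enumerate_cliques(graph: nx.Graph, min_size: int = 8,
                      max_cliques: int = 50_000) -> list[FeatureCombination]:
    """Maximal cliques of at least `min_size` features, in deterministic
    (lexicographic) order.

    Enumeration stops after `max_cliques` qualifying cliques: the number of
    maximal cliques can grow exponentially with graph density, and downstream
    stages only ever sample a fixed number of combinations.
    """
    cliques = []
    for c in nx.find_cliques(graph):
        if len(c) >= min_size:
            cliques.append(tuple(sorted(c)))
            if len(cliques) >= max_cliques:
                log.warning("clique enumeration capped at %d", max_cliques)
                break
    cliques.sort()
    log.info("found %d maximal cliques of size >= %d", len(cliques), min_size)
    return [FeatureCombination(features=c, origin_clique=i)
            for i, c in enumerate(cliques)]


def sample_combinations(cliques: list[FeatureCombination], n: int = 1600,
                        seed: int | np.random.SeedSequence = 0
                        ) -> list[FeatureCombination]:
    """Uniform sample without replacement of min(n, available) combinations."""
    rng = np.random.default_rng(seed)
    if len(cliques) <= n:
        if len(cliques) < n:
            log.warning("only %d combinations available, %d requested; using all",
                        len(cliques), n)
        return list(cliques)
    idx = rng.choice(len(cliques), size=n, replace=False)
    return [cliques[i] for i in sorted(idx)]


def select_combinations(table: FeatureTable, positive: Group,
                        control: Group = Group.C, alpha: float = 0.3,
                        corr_threshold: float = 0.3, min_clique_size: int = 8,
                        n_combinations: int = 1600,
                        seed: int | np.random.SeedSequence = 0
                        ) -> tuple[list[FeatureCombination], dict]:
    """The full funnel for one task. Returns the sampled combinations and a
    stage-count log (features kept, cliques found, combinations sampled)."""
    task_table = table.subset(table.feature_names)
    mask = task_table.labels.isin([positive, control])
    task_table = FeatureTable(task_table.frame[mask], task_table.labels[mask],
                              table.registry_version)
    kept = welch_filter(task_table, positive, control, alpha)
    graph = build_low_correlation_graph(task_table.subset(kept), corr_threshold)
    cliques = enumerate_cliques(graph, min_clique_size)
    combos = sample_combinations(cliques, n_combinations, seed)
    counts = {"features_in": len(table.feature_names), "welch_kept": len(kept),
              "cliques": len(cliques), "combinations": len(combos)}
    return combos, counts
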