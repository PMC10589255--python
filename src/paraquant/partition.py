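"""Monte Carlo test of equal expression partitioning among paralogs.

The null model is that every one of k paralogs contributes an equal 1/k
share of the family's total expression, so the k*m replicate-level RPKM
values of a strain are exchangeable across paralog slots. Each permutation
pools all values and randomly reassigns them, m per paralog; per paralog,
one-sided probabilities of seeing a permuted mean at least as high (p_high)
or as low (p_low) as the observed mean are estimated with add-one
smoothing:

    p_high = (1 + #{permuted mean >= observed}) / (n_permutations + 1)

Both directions across all paralogs (2k tests) are Benjamini–Hochberg
adjusted within the strain; a paralog is called "higher" or "lower" when
the corresponding adjusted p-value falls below alpha, otherwise
"consistent" with equal partitioning.

For small k*m an exhaustive mode enumerates every distinct assignment of
values to a paralog slot (all C(k*m, m) subsets) and reports exact
probabilities without smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class PartitionResult:
    strain: str
    table: pd.DataFrame  # paralog, observed_mean, p_high, p_low, adj, call
    params: dict = field(default_factory=dict)

    def calls(self) -> dict[str, str]:
        return dict(zip(self.table["paralog"], self.table["call"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _observed_means(values: np.ndarray) -> np.ndarray:
    return values.mean(axis=1)


def monte_carlo_partition(values, paralog_ids=None, n_permutations: int = 10_000,
                          alpha: float = 0.05, seed: int | None = None,
                          method: str = "monte-carlo", strain: str = "",
                          ) -> PartitionResult:
    """Test each paralog's mean contribution against equal partitioning.

    Parameters
    ----------
    values
        k x m array of non-negative RPKM values (k paralogs, m replicates).
        RPKM scale, not log: the test concerns shares of total expression.
    paralog_ids
        Optional k labels; defaults to row indices.
    n_permutations
        Permutations for the Monte Carlo null (ignored in exhaustive mode).
    seed
        Required in monte-carlo mode; recorded in params.
    method
        "monte-carlo" or "exhaustive" (enumerates all C(k*m, m) subsets).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 2:
        raise ValueError("values must be a k x m matrix")
    k, m = vals.shape
    if k < 2 or m < 2 or k * m < 4:
        raise ValueError("degenerate permutation space: need k>=2 paralogs "
                         "and m>=2 replicates")
    if (vals < 0).any():
        raise ValueError("negative expression values")
    if paralog_ids is None:
        paralog_ids = [str(i) for i in range(k)]
    if len(paralog_ids) != k:
        raise ValueError("paralog_ids length does not match rows")

    observed = _observed_means(vals)
    pool = vals.ravel()

    if method == "exhaustive":
        subset_means = np.array([pool[list(c)].mean()
                                 for c in combinations(range(k * m), m)])
        n_tot = subset_means.size
        p_high = np.array([(subset_means >= obs).sum() / n_tot
                           for obs in observed])
        p_low = np.array([(subset_means <= obs).sum() / n_tot
                          for obs in observed])
        params = dict(method="exhaustive", n_assignments=int(n_tot),
                      alpha=alpha)
    elif method == "monte-carlo":
        if seed is None:
            raise ValueError("seed is required for the Monte Carlo null")
        rng = np.random.default_rng(seed)
        perms = rng.permuted(
            np.broadcast_to(pool, (n_permutations, k * m)).copy(), axis=1)
        perm_means = perms.reshape(n_permutations, k, m).mean(axis=2)
        p_high = (1 + (perm_means >= observed).sum(axis=0)) / (n_permutations + 1)
        p_low = (1 + (perm_means <= observed).sum(axis=0)) / (n_permutations + 1)
        params = dict(method="monte-carlo", n_permutations=n_permutations,
                      alpha=alpha, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")

    adj = multipletests(np.concatenate([p_high, p_low]), method="fdr_bh")[1]
    p_high_adj, p_low_adj = adj[:k], adj[k:]
    calls = np.where(p_high_adj < alpha, "higher",
                     np.where(p_low_adj < alpha, "lower", "consistent"))
    table = pd.DataFrame(dict(paralog=paralog_ids, observed_mean=observed,
                              p_high=p_high, p_low=p_low,
                              p_high_adj=p_high_adj, p_low_adj=p_low_adj,
                              call=calls))
    return PartitionResult(strain=strain, table=table, params=params)


def partition_by_strain(matrix: pd.DataFrame, n_permutations: int = 10_000,
                        alpha: float = 0.05, seed: int | None = None,
                        value_col: str = "rpkm") -> dict[str, PartitionResult]:
    """Run the partition test per strain from the long expression frame
    (columns strain, target, replicate, rpkm; family 'ALL' rows and
    unreliable rows are excluded)."""
    out = {}
    sub = matrix.loc[matrix["target"] != "ALL"]
    if "reliable" in sub.columns:
        sub = sub.loc[sub["reliable"]]
    for s_idx, (strain, g) in enumerate(sub.groupby("strain")):
        wide = g.pivot_table(index="target", columns="replicate",
                             values=value_col)
        if wide.isna().any().any():
            raise ValueError(f"missing replicate values for strain {strain}")
        strain_seed = None if seed is None else (seed + s_idx) % (2 ** 31)
        out[strain] = monte_carlo_partition(
            wide.to_numpy(), paralog_ids=list(wide.index),
            n_permutations=n_permutations, alpha=alpha, seed=strain_seed,
            strain=strain)
    return out
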