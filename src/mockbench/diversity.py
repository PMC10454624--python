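"""Alpha and beta diversity for amplicon count tables.

Alpha diversity (within-sample): counts are normalized by rarefaction
(single seeded subsample without replacement to a common depth), then the
inverse Simpson index and Pielou's evenness are computed.  Beta diversity
(between-sample): counts are treated as compositions — a pseudocount is
added, samples are centered-log-ratio (CLR) transformed, and inter-sample
distances are Euclidean in CLR space (the Aitchison distance).  Ordination
is classical principal coordinates analysis (PCoA) and group effects are
tested with PERMANOVA (permutation F-test on the distance matrix).
Everything here is computed from first principles on numpy arrays; the
statistics are simple enough that the formulas are the documentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TaxonomicLineage


@dataclass
class FeatureTable:
    """Features × samples integer counts with optional feature lineages."""

    counts: pd.DataFrame
    lineages: dict[str, TaxonomicLineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample names")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def collapse(self, rank: str) -> "FeatureTable":
        """Sum feature counts within each taxon label at ``rank``.

        Features without a lineage (or unclassified at that rank) collapse
        into their own feature id.
        """
        labels = [
            (self.lineages[f].label(rank) or f) if f in self.lineages else f
            for f in self.counts.index
        ]
        collapsed = self.counts.groupby(labels, sort=True).sum()
        return FeatureTable(collapsed)

    def rarefy(self, depth: int, seed: int) -> "FeatureTable":
        """Rarefy every sample to ``depth``; shallower samples are dropped
        with a warning (they cannot be subsampled to that depth)."""
        rng = np.random.default_rng(seed)
        keep: dict[str, np.ndarray] = {}
        for sample in self.samples:
            col = self.counts[sample].to_numpy()
            if col.sum() < depth:
                warnings.warn(
                    f"sample {sample!r} has {int(col.sum())} < depth {depth}; "
                    "excluded from rarefaction", stacklevel=2)
                continue
            keep[sample] = rarefy(col, depth, rng)
        return FeatureTable(pd.DataFrame(keep, index=self.counts.index))


def rarefy(counts: np.ndarray, depth: int,
           rng: int | np.random.Generator) -> np.ndarray:
    """Subsample one sample's counts to ``depth`` reads without replacement.

    The result always sums exactly to ``depth`` and is reproducible for a
    given seed/generator state.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.astype(np.int64).copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # draw read indices without replacement; map back to features via cumsum
    chosen = rng.choice(total, size=depth, replace=False)
    edges = np.cumsum(counts)
    feature_of = np.searchsorted(edges, chosen, side="right")
    return np.bincount(feature_of, minlength=len(counts)).astype(np.int64)


def inverse_simpson(counts: np.ndarray) -> float:
    """Inverse Simpson diversity 1 / Σ p_i²; n for a uniform sample of n."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = counts / total
    return float(1.0 / np.sum(p ** 2))


def pielou(counts: np.ndarray) -> float | None:
    """Pielou's evenness J = H / ln(S) over observed (nonzero) features.

    H is Shannon entropy with natural logs; S the number of nonzero
    features.  Undefined (None) when fewer than two features are observed.
    """
    counts = np.asarray(counts, dtype=float)
    nz = counts[counts > 0]
    if len(nz) < 2:
        return None
    p = nz / nz.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(len(nz)))


def clr(composition: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform with additive pseudocount.

    The pseudocount (> 0) is added to every entry before closure so zeros
    are representable.  The output sums to zero and is invariant to overall
    scaling of the input.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.asarray(composition, dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("nonpositive entries after pseudocount")
    logx = np.log(x)
    return logx - logx.mean()


def aitchison_matrix(table: pd.DataFrame | FeatureTable,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Pairwise Aitchison distances between samples (columns).

    Euclidean distance between CLR-transformed sample vectors; a metric,
    since it is an isometry of Euclidean space.
    """
    counts = table.counts if isinstance(table, FeatureTable) else table
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    z = np.stack([clr(counts[s].to_numpy(), pseudocount)
                  for s in counts.columns])
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


def pcoa(dist: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal coordinates analysis (metric MDS).

    Double-centers -D²/2, eigendecomposes, and returns sample coordinates
    on axes with positive eigenvalues (ordered by eigenvalue) along with
    the fraction of positive-eigenvalue variance each axis explains.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.any(d > 0):
        raise ValueError("all-zero distance matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    explained = eigval[pos] / eigval[pos].sum()
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dist.index, columns=cols), explained


def _permanova_ss_within(d2: np.ndarray, labels: np.ndarray,
                         groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss


def permanova(dist: pd.DataFrame, groups: Mapping[str, str] | Sequence[str],
              n_perm: int = 999, seed: int = 0,
              ) -> tuple[float, float, float]:
    """One-way PERMANOVA on a distance matrix.

    Partitions the total sum of squared distances into between- and
    within-group components; the pseudo-F statistic is compared with its
    distribution under ``n_perm`` random relabellings.  Returns
    (pseudo_F, R², p) with R² = SS_between / SS_total and
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if isinstance(groups, Mapping):
        labels = np.array([groups[s] for s in dist.index])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != len(dist.index):
            raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")

    d2 = dist.to_numpy(dtype=float) ** 2
    n, a = len(labels), len(uniq)
    ss_total = d2.sum() / (2 * n)
    ss_within = _permanova_ss_within(d2, labels, uniq)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ss_w = _permanova_ss_within(d2, perm, uniq)
        f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(f_obs), float(r2), float(p)


def pairwise_permanova(dist: pd.DataFrame, groups: Mapping[str, str],
                       n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """PERMANOVA for every pair of groups (as comparisons are reported)."""
    labels = pd.Series({s: groups[s] for s in dist.index})
    uniq = sorted(labels.unique())
    rows = []
    for i, g1 in enumerate(uniq):
        for g2 in uniq[i + 1:]:
            samples = labels.index[labels.isin([g1, g2])]
            sub = dist.loc[samples, samples]
            f, r2, p = permanova(sub, labels[samples], n_perm, seed)
            rows.append({"group1": g1, "group2": g2,
                         "pseudo_F": f, "R2": r2, "p_value": p})
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Paired two-sided Student's t-test on matched measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
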