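"""Binary-trait statistics: frequency estimates, pairwise exact tests and
post-hoc grouping.

The trait is the once-per-animal division of the P3.p vulval precursor cell,
scored as divided/not-divided over replicates of >= 50 isogenic animals.
Replicates of one strain are pooled before testing; all strain pairs are
compared with two-sided Fisher exact tests and Benjamini-Hochberg FDR
control, and strains are grouped by a compact letter display over the
non-significance graph.  Confidence intervals are continuity-corrected
Wilson score intervals (the convention of R's ``prop.test``), with exact
Clopper-Pearson available behind a flag.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import PhenotypeRecord, PipelineError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FreqEstimate:
    """Pooled division frequency of one strain with a 95% CI."""

    strain: str
    n_divided: int
    n_scored: int
    freq: float
    ci95: tuple[float, float]


class LineClass(enum.Enum):
    """Post-hoc class of a backcrossed line relative to ancestor and MA parent."""

    MA_LIKE = "ma_like"  # red: differs from ancestor, not from MA parent
    ANCESTOR_LIKE = "ancestor_like"  # blue: differs from MA parent, not ancestor
    AMBIGUOUS = "ambiguous"  # gray: differs from both or from neither


@dataclass
class PairwiseTestMatrix:
    """Symmetric matrices of raw and BH-adjusted two-sided Fisher p-values."""

    strains: list[str]
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float = 0.05

    def index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise PipelineError(f"strain {strain!r} not in test matrix") from None

    def adjusted(self, a: str, b: str) -> float:
        return float(self.p_adj[self.index(a), self.index(b)])


def pool_records(
    records: Iterable[PhenotypeRecord], heterogeneity_alpha: float = 0.01
) -> dict[str, tuple[int, int]]:
    """Pool replicates per strain into (n_divided, n_scored) totals.

    Replicate heterogeneity (any within-strain replicate pair with Fisher
    p < ``heterogeneity_alpha``) is logged as a warning but does not change
    pooling.
    """
    by_strain: dict[str, list[PhenotypeRecord]] = {}
    for rec in records:
        by_strain.setdefault(rec.strain, []).append(rec)
    pooled: dict[str, tuple[int, int]] = {}
    for strain, recs in by_strain.items():
        for r1, r2 in itertools.combinations(recs, 2):
            table = [
                [r1.n_divided, r1.n_scored - r1.n_divided],
                [r2.n_divided, r2.n_scored - r2.n_divided],
            ]
            if stats.fisher_exact(table)[1] < heterogeneity_alpha:
                logger.warning(
                    "strain %s: replicates %s and %s are heterogeneous; "
                    "pooling anyway",
                    strain,
                    r1.replicate,
                    r2.replicate,
                )
                break
        pooled[strain] = (
            sum(r.n_divided for r in recs),
            sum(r.n_scored for r in recs),
        )
    return pooled


def wilson_cc_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction, truncated to [0, 1].

    Closed form matching R's ``prop.test`` with ``correct = TRUE``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    p = x / n
    z2 = z * z
    denom = 2 * (n + z2)
    if x == 0:
        lower = 0.0
    else:
        lower = (
            2 * n * p + z2 - 1 - z * math.sqrt(z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
        ) / denom
    if x == n:
        upper = 1.0
    else:
        upper = (
            2 * n * p + z2 + 1 + z * math.sqrt(z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
        ) / denom
    return (max(0.0, lower), min(1.0, upper))


def division_frequency_ci(
    records: Iterable[PhenotypeRecord],
    conf: float = 0.95,
    method: str = "wilson_cc",
) -> FreqEstimate:
    """Pooled division frequency of one strain with a score CI.

    All records must belong to the same strain.  ``method`` is
    ``"wilson_cc"`` (default) or ``"clopper_pearson"``.
    """
    recs = list(records)
    if not recs:
        raise ValidationError("no phenotype records supplied")
    strains = {r.strain for r in recs}
    if len(strains) > 1:
        raise ValidationError(f"records span several strains: {sorted(strains)}")
    x = sum(r.n_divided for r in recs)
    n = sum(r.n_scored for r in recs)
    if method == "wilson_cc":
        ci = wilson_cc_interval(x, n, conf)
    elif method == "clopper_pearson":
        a = (1 - conf) / 2
        lower = 0.0 if x == 0 else float(stats.beta.ppf(a, x, n - x + 1))
        upper = 1.0 if x == n else float(stats.beta.ppf(1 - a, x + 1, n - x))
        ci = (lower, upper)
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    return FreqEstimate(
        strain=recs[0].strain, n_divided=x, n_scored=n, freq=x / n, ci95=ci
    )


def pairwise_fisher_fdr(
    counts: Mapping[str, tuple[int, int]],
    alpha: float = 0.05,
) -> PairwiseTestMatrix:
    """All pairwise two-sided Fisher exact tests with BH adjustment.

    ``counts`` maps strain -> pooled (n_divided, n_scored).  The BH family
    is the strict upper triangle of the pair matrix (every strain pair in
    this analysis run); adjusted values are mirrored into a symmetric matrix
    with a unit diagonal.
    """
    strains = list(counts)
    if len(strains) < 2:
        raise PipelineError("need at least two strains for pairwise tests")
    k = len(strains)
    p_raw = np.ones((k, k))
    pairs = list(itertools.combinations(range(k), 2))
    raw_list = []
    for i, j in pairs:
        xi, ni = counts[strains[i]]
        xj, nj = counts[strains[j]]
        _, p = stats.fisher_exact([[xi, ni - xi], [xj, nj - xj]])
        p_raw[i, j] = p_raw[j, i] = p
        raw_list.append(p)
    p_adj = np.ones((k, k))
    if raw_list:
        adj = multipletests(raw_list, alpha=alpha, method="fdr_bh")[1]
        for (i, j), a in zip(pairs, adj):
            p_adj[i, j] = p_adj[j, i] = a
    return PairwiseTestMatrix(strains=strains, p_raw=p_raw, p_adj=p_adj, alpha=alpha)


def classify_backcross_line(
    line: str,
    ancestor: str,
    ma_parent: str,
    matrix: PairwiseTestMatrix,
) -> LineClass:
    """Assign a backcrossed line to the red/blue/gray post-hoc class.

    ma_like (red): significantly different from the ancestor but not from
    the MA parent; ancestor_like (blue): the mirror; ambiguous (gray):
    different from both or from neither.
    """
    alpha = matrix.alpha
    vs_anc = matrix.adjusted(line, ancestor)
    vs_ma = matrix.adjusted(line, ma_parent)
    if vs_anc < alpha and vs_ma >= alpha:
        return LineClass.MA_LIKE
    if vs_ma < alpha and vs_anc >= alpha:
        return LineClass.ANCESTOR_LIKE
    return LineClass.AMBIGUOUS


def compact_letter_display(matrix: PairwiseTestMatrix) -> dict[str, str]:
    """Letter groups such that strains sharing no letter differ significantly.

    Insert-and-absorb over the non-significance graph: start from one group
    holding every strain; for each significant pair split every group
    containing both members; absorb groups that became subsets of others.
    Deterministic given the strain order of the matrix.
    """
    strains = matrix.strains
    alpha = matrix.alpha
    groups: list[set[str]] = [set(strains)]
    for i, j in itertools.combinations(range(len(strains)), 2):
        if matrix.p_adj[i, j] >= alpha:
            continue
        a, b = strains[i], strains[j]
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {b})  # group keeping the earlier strain
                new_groups.append(g - {a})
            else:
                new_groups.append(g)
        # absorb: drop empties, duplicates and proper subsets of other groups
        uniq: list[set[str]] = []
        for g in new_groups:
            if g and g not in uniq:
                uniq.append(g)
        groups = [g for g in uniq if not any(g < other for other in uniq)]
    order = {s: i for i, s in enumerate(strains)}
    groups.sort(key=lambda g: min(order[s] for s in g))
    letters = {}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, g in enumerate(groups):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for s in g:
            letters.setdefault(s, [])
            letters[s].append(letter)
    return {s: "".join(sorted(letters.get(s, []))) for s in strains}
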