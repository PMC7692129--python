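"""Allele-frequency statistics for evaluative variants.

For each scored variant, every reporting laboratory contributes its MRAF
(median allelic frequency over its up-to-three replicates). The consensus
value MAF is the median of participant MRAFs after iterative two-sided
Grubbs outlier removal; SD is the n-1 sample standard deviation of the
retained MRAFs. Each reporter then receives Z = (MRAF - MAF) / SD and a
citation when |Z| exceeds the acceptance threshold (3.0). Laboratories
removed as outliers still receive a Z against the trimmed consensus - they
are exactly the ones the citation is meant to flag.

In peer-group mode (benchmarks where panels differ enough that allele
frequencies are only comparable within a panel), the consensus and Z are
computed within each peer group, and no Z is allocated in groups with
fewer than ``peer_group_min`` (default 6) reporting members.

Shapiro-Wilk normality p-values are attached for reporting only; they
never gate scoring.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .nomenclature import VariantKey


@dataclass(frozen=True)
class ZResult:
    z: Optional[float]
    allocated: bool
    cited: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.cited and not self.allocated:
            raise ValueError("a citation requires an allocated Z")
        if not self.allocated and self.z is not None:
            raise ValueError("unallocated Z must be undefined")


@dataclass(frozen=True)
class PeerGroup:
    panel_id: str
    members: tuple[str, ...]


class AllocationMode(str, enum.Enum):
    GLOBAL = "global"
    PEER_GROUP = "peer_group"


@dataclass
class GroupStats:
    """Trimmed consensus statistics for one allocation pool."""

    group_id: str
    maf: float
    sd: float
    n_used: int
    outliers_removed: tuple[str, ...]
    shapiro_p: Optional[float]


@dataclass
class VariantStatistics:
    key: VariantKey
    sample_id: str
    mraf_by_participant: dict[str, float]
    maf: Optional[float] = None
    sd: Optional[float] = None
    n_used: int = 0
    outliers_removed: tuple[str, ...] = ()
    shapiro_p: Optional[float] = None
    z_by_participant: dict[str, ZResult] = field(default_factory=dict)
    group_stats: dict[str, GroupStats] = field(default_factory=dict)

    @property
    def cited(self) -> int:
        return sum(1 for z in self.z_by_participant.values() if z.cited)

    @property
    def allocated(self) -> int:
        return sum(1 for z in self.z_by_participant.values() if z.allocated)


def mraf(replicate_afs: Sequence[float]) -> Optional[float]:
    """Median allelic frequency over a participant's reported replicates."""
    if len(replicate_afs) == 0:
        return None
    return float(np.median(np.asarray(replicate_afs, dtype=float)))


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G(n, alpha).

    G = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def trimmed_stats(
    mrafs: dict[str, float], alpha: float = 0.05
) -> tuple[Optional[float], Optional[float], dict[str, float], tuple[str, ...]]:
    """Iterative two-sided Grubbs trimming, then median and sample SD.

    Returns ``(maf, sd, retained, removed)``. The most extreme value is
    removed while its Grubbs statistic exceeds the critical value and at
    least three values remain; SD uses the n-1 denominator on the retained
    values (0 for a single value).
    """
    if not mrafs:
        return None, None, {}, ()
    retained = dict(mrafs)
    removed: list[str] = []
    while len(retained) >= 3:
        labs = list(retained)
        values = np.array([retained[p] for p in labs], dtype=float)
        mean = values.mean()
        s = values.std(ddof=1)
        if s == 0:
            break
        deviations = np.abs(values - mean)
        i = int(np.argmax(deviations))
        g = deviations[i] / s
        if g <= grubbs_critical_value(len(values), alpha):
            break
        removed.append(labs[i])
        del retained[labs[i]]
    vals = np.array(list(retained.values()), dtype=float)
    maf = float(np.median(vals))
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return maf, sd, retained, tuple(removed)


def z_score(mraf_p: float, maf: float, sd: float, z_acceptance: float = 3.0) -> ZResult:
    """Z = (MRAF - MAF) / SD with degenerate-spread handling.

    With sd == 0 a distribution cannot be formed: a participant sitting on
    the consensus gets z = 0, any other is flagged degenerate and left
    unallocated rather than assigned an infinite score.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        if mraf_p == maf:
            return ZResult(z=0.0, allocated=True, cited=False, degenerate=True)
        return ZResult(z=None, allocated=False, cited=False, degenerate=True)
    z = (mraf_p - maf) / sd
    return ZResult(z=z, allocated=True, cited=abs(z) > z_acceptance)


def shapiro_flag(values: Sequence[float]) -> Optional[float]:
    """Shapiro-Wilk p-value, or None for degenerate/too-small samples."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 3 or np.ptp(arr) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(arr).pvalue)


def _allocate_pool(
    stats_obj: VariantStatistics,
    pool: Sequence[str],
    group_id: str,
    alpha: float,
    z_acceptance: float,
) -> None:
    pool_mrafs = {p: stats_obj.mraf_by_participant[p] for p in pool}
    maf, sd, retained, removed = trimmed_stats(pool_mrafs, alpha=alpha)
    gs = GroupStats(
        group_id=group_id,
        maf=maf,  # type: ignore[arg-type]
        sd=sd,  # type: ignore[arg-type]
        n_used=len(retained),
        outliers_removed=removed,
        shapiro_p=shapiro_flag(list(retained.values())),
    )
    stats_obj.group_stats[group_id] = gs
    for p in pool:
        stats_obj.z_by_participant[p] = z_score(
            pool_mrafs[p], maf, sd, z_acceptance  # type: ignore[arg-type]
        )


def allocate_z(
    key: VariantKey,
    sample_id: str,
    mraf_by_participant: dict[str, float],
    mode: AllocationMode = AllocationMode.GLOBAL,
    groups: Sequence[PeerGroup] = (),
    peer_group_min: int = 6,
    alpha: float = 0.05,
    z_acceptance: float = 3.0,
) -> VariantStatistics:
    """Compute trimmed statistics and allocate Z-scores for one variant."""
    st = VariantStatistics(
        key=key, sample_id=sample_id, mraf_by_participant=dict(mraf_by_participant)
    )
    reporters = list(mraf_by_participant)
    for p in reporters:
        st.z_by_participant[p] = ZResult(z=None, allocated=False, cited=False)

    if mode is AllocationMode.GLOBAL:
        if len(reporters) >= 2:
            _allocate_pool(st, reporters, "global", alpha, z_acceptance)
        pool_id = "global"
    else:
        grouped: set[str] = set()
        for g in groups:
            pool = [p for p in g.members if p in mraf_by_participant]
            grouped.update(pool)
            if len(pool) >= peer_group_min:
                _allocate_pool(st, pool, g.panel_id, alpha, z_acceptance)
        stray = set(reporters) - grouped
        if stray:
            warnings.warn(
                f"reporters without a peer group left unallocated: {sorted(stray)}"
            )
        pool_id = None

    # Headline MAF/SD: the (unique) allocated pool when one exists, else
    # trimmed stats over all reporters, for display only.
    if pool_id and pool_id in st.group_stats:
        gs = st.group_stats[pool_id]
    elif len(st.group_stats) == 1:
        gs = next(iter(st.group_stats.values()))
    else:
        gs = None
    if gs is not None:
        st.maf, st.sd = gs.maf, gs.sd
        st.n_used = gs.n_used
        st.outliers_removed = gs.outliers_removed
        st.shapiro_p = gs.shapiro_p
    elif reporters:
        maf, sd, retained, removed = trimmed_stats(mraf_by_participant, alpha=alpha)
        st.maf, st.sd, st.n_used, st.outliers_removed = maf, sd, len(retained), removed
        st.shapiro_p = shapiro_flag(list(retained.values()))
    return st
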