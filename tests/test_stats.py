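"""Robust AF statistics against independent brute-force references."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from eqapt.nomenclature import VariantKey
from eqapt.stats import (
    AllocationMode,
    PeerGroup,
    allocate_z,
    grubbs_critical_value,
    mraf,
    shapiro_flag,
    trimmed_stats,
    z_score,
)

KEY = VariantKey(gene="BRAF", canonical_p="p.(Val600Glu)")


# ---------------------------------------------------------------- reference
def ref_median(values):
    """Textbook median: middle of the sorted values, mean of two middles."""
    v = sorted(values)
    n = len(v)
    return v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2.0


def ref_grubbs_once(values, alpha):
    """One Grubbs step by direct formula; returns index to drop or None."""
    n = len(values)
    if n < 3:
        return None
    mean = sum(values) / n
    s = math.sqrt(sum((x - mean) ** 2 for x in values) / (n - 1))
    if s == 0:
        return None
    idx = max(range(n), key=lambda i: abs(values[i] - mean))
    g = abs(values[idx] - mean) / s
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
    return idx if g > crit else None


def ref_trimmed(values, alpha=0.05):
    vals = list(values)
    while True:
        idx = ref_grubbs_once(vals, alpha)
        if idx is None:
            break
        vals.pop(idx)
    m = ref_median(vals)
    if len(vals) > 1:
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((x - mean) ** 2 for x in vals) / (len(vals) - 1))
    else:
        sd = 0.0
    return m, sd, len(vals)


# ------------------------------------------------------------------- tests
@pytest.mark.parametrize(
    "values, expected",
    [([35.1, 35.7, 36.0], 35.7), ([10.0, 14.0], 12.0), ([7.3], 7.3)],
)
def test_mraf_median(values, expected):
    assert mraf(values) == pytest.approx(expected)


def test_mraf_empty_is_undefined():
    assert mraf([]) is None


def test_trimmed_stats_no_outlier():
    maf, sd, retained, removed = trimmed_stats({"A": 10.0, "B": 12.0, "C": 14.0})
    assert maf == 12.0
    assert sd == pytest.approx(2.0)
    assert removed == () and set(retained) == {"A", "B", "C"}


def test_trimmed_stats_removes_constructed_outlier():
    data = {"A": 10.0, "B": 10.2, "C": 10.1, "D": 9.9, "E": 10.0, "F": 25.0}
    maf, sd, retained, removed = trimmed_stats(data, alpha=0.05)
    assert removed == ("F",)
    ref_m, ref_sd, ref_n = ref_trimmed(data.values())
    assert maf == pytest.approx(ref_m) and sd == pytest.approx(ref_sd)
    assert len(retained) == ref_n == 5


def test_trimmed_stats_constant_sample():
    maf, sd, retained, removed = trimmed_stats({c: 8.0 for c in "ABCDE"})
    assert maf == 8.0 and sd == 0.0 and removed == ()


def test_trimmed_stats_small_n_no_grubbs():
    maf, sd, retained, removed = trimmed_stats({"A": 1.0, "B": 99.0})
    assert removed == ()  # n < 3: no test performed
    assert maf == 50.0


def test_trimmed_stats_matches_bruteforce_on_random_samples():
    rng = np.random.default_rng(20170101)
    for _ in range(1000):
        n = int(rng.integers(1, 11))
        vals = np.round(rng.uniform(0, 60, n) + rng.choice([0, 40], n, p=[0.9, 0.1]), 3)
        data = {f"P{i}": float(v) for i, v in enumerate(vals)}
        maf, sd, retained, removed = trimmed_stats(data)
        ref_m, ref_sd, ref_n = ref_trimmed(vals.tolist())
        assert maf == pytest.approx(ref_m, abs=1e-9)
        assert sd == pytest.approx(ref_sd, abs=1e-9)
        assert len(retained) == ref_n


def test_grubbs_critical_value_textbook_case():
    # published two-sided table value for n=8, alpha=0.05 is 2.1266
    assert grubbs_critical_value(8, 0.05) == pytest.approx(2.1266, abs=2e-4)


@pytest.mark.parametrize(
    "mraf_p, maf, sd, z, cited",
    [(12.0, 12.0, 2.0, 0.0, False), (14.0, 12.0, 2.0, 1.0, False),
     (19.0, 12.0, 2.0, 3.5, True), (5.9, 12.0, 2.0, -3.05, True)],
)
def test_z_score_threshold(mraf_p, maf, sd, z, cited):
    res = z_score(mraf_p, maf, sd)
    assert res.z == pytest.approx(z)
    assert res.cited is cited and res.allocated


def test_z_score_degenerate_spread():
    on = z_score(10.0, 10.0, 0.0)
    assert on.z == 0.0 and on.allocated and not on.cited and on.degenerate
    off = z_score(11.0, 10.0, 0.0)
    assert off.z is None and not off.allocated and not off.cited


def test_z_shift_scale_equivariance():
    rng = np.random.default_rng(7)
    base = {f"P{i}": float(v) for i, v in enumerate(rng.uniform(5, 40, 12))}
    st0 = allocate_z(KEY, "S", base)
    for c, k in [(7.0, 1.0), (0.0, 1.9), (3.0, 1.3)]:
        other = {p: k * v + c for p, v in base.items()}
        st1 = allocate_z(KEY, "S", other)
        for p in base:
            assert st1.z_by_participant[p].z == pytest.approx(
                st0.z_by_participant[p].z, abs=1e-9
            )


def test_citations_nonincreasing_in_acceptance_threshold():
    rng = np.random.default_rng(11)
    vals = {f"P{i}": float(v) for i, v in enumerate(rng.normal(20, 1, 15))}
    vals["OUT"] = 90.0
    cited = [
        sum(z.cited for z in allocate_z(KEY, "S", vals, z_acceptance=t).z_by_participant.values())
        for t in (1.0, 2.0, 3.0, 4.0, 10.0)
    ]
    assert cited == sorted(cited, reverse=True)


def test_median_reporter_has_zero_z_when_n_odd():
    vals = {f"P{i}": v for i, v in enumerate([10.0, 11.0, 12.0, 13.0, 14.0])}
    st = allocate_z(KEY, "S", vals)
    assert st.z_by_participant["P2"].z == pytest.approx(0.0)


def test_removed_outlier_still_gets_allocated_z():
    vals = {f"P{i}": float(v) for i, v in enumerate([10, 10.3, 9.8, 10.1, 9.9, 10.2])}
    vals["OUT"] = 60.0
    st = allocate_z(KEY, "S", vals)
    assert "OUT" in st.outliers_removed
    out = st.z_by_participant["OUT"]
    assert out.allocated and out.cited and out.z > 3


def test_single_reporter_not_allocated():
    st = allocate_z(KEY, "S", {"P0": 12.0})
    assert st.allocated == 0
    assert not st.z_by_participant["P0"].allocated


def test_peer_group_minimum_membership():
    vals = {f"A{i}": 10.0 + 0.1 * i for i in range(7)}
    vals.update({f"B{i}": 10.0 + 0.1 * i for i in range(4)})
    groups = [
        PeerGroup(panel_id="pa", members=tuple(f"A{i}" for i in range(7))),
        PeerGroup(panel_id="pb", members=tuple(f"B{i}" for i in range(4))),
    ]
    st = allocate_z(KEY, "S", vals, mode=AllocationMode.PEER_GROUP, groups=groups)
    assert st.allocated == 7
    assert all(not st.z_by_participant[f"B{i}"].allocated for i in range(4))
    # consensus is computed within the qualifying group only
    assert st.group_stats["pa"].n_used == 7 and "pb" not in st.group_stats


def test_shapiro_flag_behaviour():
    rng = np.random.default_rng(123)
    hits = sum(shapiro_flag(rng.normal(20, 2, 50)) > 0.05 for _ in range(100))
    assert hits >= 90  # normal data rarely rejected
    bimodal = [10.0] + [50.0 + 0.1 * i for i in range(10)]
    assert shapiro_flag(bimodal) < 0.05
    assert shapiro_flag([5.0, 5.0, 5.0]) is None  # degenerate
    assert shapiro_flag([5.0, 6.0]) is None  # too small
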