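import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrpipe.instruments import (
    EmptyInstrumentsError, LdMatrix, clump, f_statistic, select_instruments, snp_r2,
)
from mrpipe.sumstats_io import SumStats


def _stats(rows):
    df = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"])
    return SumStats(trait_id="toy", trait_type="continuous", df=df)


def test_snp_r2_tstat_direct_arithmetic():
    # t = 0.1/0.01 = 10, r2 = 100/(100 + 10000)
    assert snp_r2(0.1, se=0.01, n=10_002, method="tstat") == pytest.approx(100 / 10100)


def test_snp_r2_tstat_vanishes_with_large_n():
    r2 = [float(snp_r2(0.1, se=0.01, n=n, method="tstat")) for n in (1e3, 1e5, 1e7, 1e9)]
    assert all(a > b for a, b in zip(r2, r2[1:]))
    assert r2[-1] < 1e-5


def test_snp_r2_eaf_direct_arithmetic():
    assert snp_r2(0.2, eaf=0.5, method="eaf") == pytest.approx(2 * 0.04 * 0.25)


def test_snp_r2_eaf_without_frequency_is_config_error():
    with pytest.raises(ValueError, match="eaf"):
        snp_r2(0.2, method="eaf")


def test_f_statistic_examples():
    # oracle: F equals the squared Wald t under the tstat R^2
    t2 = (0.1 / 0.01) ** 2
    r2 = snp_r2(0.1, se=0.01, n=10_002, method="tstat")
    assert f_statistic(r2, 10_002) == pytest.approx(t2)
    assert f_statistic(0.0, 5000) == 0.0
    assert f_statistic(0.01, 1002) == pytest.approx(1000 * 0.01 / 0.99)
    assert f_statistic(0.01, 1002) > 10  # passes the weak-instrument bound


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    r2=st.floats(1e-6, 0.5), n=st.integers(10, 10**6),
    dr=st.floats(1e-6, 0.4), dn=st.integers(1, 10**5),
)
def test_f_statistic_strictly_increasing(r2, n, dr, dn):
    f = f_statistic(r2, n)
    assert f_statistic(min(r2 + dr, 0.95), n) > f
    assert f_statistic(r2, n + dn) > f


def _block_ld(rsids, r2_within, blocks):
    k = len(rsids)
    m = np.zeros((k, k))
    for block in blocks:
        for i, j in itertools.permutations(block, 2):
            m[i, j] = r2_within
    np.fill_diagonal(m, 1.0)
    return LdMatrix(rsids=list(rsids), r2=m)


def _cand(rows):
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "beta", "se", "pval", "n", "ea", "oa", "eaf"])


def test_clump_keeps_most_significant_of_correlated_pair():
    ld = _block_ld(["rs1", "rs2"], 0.5, [[0, 1]])
    cand = _cand([("rs1", "1", 100_000, 0.1, 0.01, 1e-9, 1e4, "A", "G", 0.3),
                  ("rs2", "1", 150_000, 0.1, 0.01, 1e-8, 1e4, "A", "G", 0.3)])
    kept = clump(cand, ld, window_kb=10_000, r2_max=0.001)
    assert kept["rsid"].tolist() == ["rs1"]


def test_clump_different_chromosomes_both_retained():
    ld = _block_ld(["rs1"], 0.0, [])  # rs2 absent from the matrix entirely
    cand = _cand([("rs1", "1", 100_000, 0.1, 0.01, 1e-9, 1e4, "A", "G", 0.3),
                  ("rs2", "2", 100_000, 0.1, 0.01, 1e-8, 1e4, "A", "G", 0.3)])
    kept = clump(cand, ld, window_kb=10_000, r2_max=0.001)
    assert sorted(kept["rsid"]) == ["rs1", "rs2"]


def _greedy_oracle(cand, ld, window_kb, r2_max):
    """Independent replay: explicit greedy scan over (pval, rsid)-sorted rows."""
    rows = sorted(cand.to_dict("records"), key=lambda r: (r["pval"], r["rsid"]))
    acc = []
    for r in rows:
        ok = True
        for a in acc:
            if a["chrom"] != r["chrom"] or abs(a["pos"] - r["pos"]) > window_kb * 1000:
                continue
            r2 = ld.get(r["rsid"], a["rsid"])
            if r2 is not None and r2 >= r2_max:
                ok = False
        if ok:
            acc.append(r)
    return [r["rsid"] for r in acc]


def test_clump_block_matrix_matches_greedy_oracle():
    rsids = [f"rs{i}" for i in range(5)]
    ld = _block_ld(rsids, 0.8, [[0, 1, 2], [3, 4]])
    cand = _cand([(rsids[i], "1", 100_000 * (i + 1), 0.1, 0.01, p, 1e4, "A", "G", 0.3)
                  for i, p in enumerate([1e-8, 1e-9, 1e-7, 1e-6, 1e-10])])
    kept = clump(cand, ld, window_kb=10_000, r2_max=0.001)
    assert kept["rsid"].tolist() == _greedy_oracle(cand, ld, 10_000, 0.001)
    assert sorted(kept["rsid"]) == ["rs1", "rs4"]  # one per block, smallest p


def test_clump_invariant_to_input_row_order():
    rng = np.random.default_rng(0)
    rsids = [f"rs{i}" for i in range(8)]
    ld = _block_ld(rsids, 0.6, [[0, 1, 2, 3], [4, 5, 6, 7]])
    cand = _cand([(rsids[i], "1", 50_000 * (i + 1), 0.1, 0.01, float(p), 1e4, "A", "G", 0.3)
                  for i, p in enumerate(rng.uniform(1e-10, 1e-6, 8))])
    base = clump(cand, ld)["rsid"].tolist()
    for seed in range(3):
        shuffled = cand.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        assert clump(shuffled, ld)["rsid"].tolist() == base


def _six_snp_table():
    # 2 above threshold, of the remaining 4: one blacklisted, one palindromic
    return _stats([
        ("rs1", "1", 100_000, "A", "G", 0.3, 0.10, 0.010, 1e-9, 1e4),
        ("rs2", "1", 20_000_000, "C", "T", 0.3, 0.09, 0.010, 1e-8, 1e4),
        ("rs3", "1", 40_000_000, "A", "G", 0.3, 0.08, 0.010, 1e-7, 1e4),   # blacklisted
        ("rs4", "1", 60_000_000, "A", "T", 0.3, 0.08, 0.010, 1e-7, 1e4),   # palindromic
        ("rs5", "2", 100_000, "A", "G", 0.3, 0.02, 0.010, 1e-3, 1e4),      # fails p
        ("rs6", "2", 200_000, "G", "A", 0.3, 0.01, 0.010, 0.5, 1e4),       # fails p
    ])


def test_select_instruments_stage_counts_conserved():
    stats = _six_snp_table()
    inst = select_instruments(stats, p_threshold=1e-6, exclusion=["rs3"])
    assert sorted(inst.df["rsid"]) == ["rs1", "rs2"]
    prov = inst.provenance
    removed = sum(v for k, v in prov.items() if k.startswith("removed_"))
    assert prov["input"] == prov["retained"] + removed
    assert prov["removed_pval"] == 2
    assert prov["removed_exclusion"] == 1
    assert prov["removed_palindromic"] == 1
    assert (inst.df["f_stat"] > 10).all()


def test_select_instruments_empty_at_p_filter_names_stage():
    stats = _six_snp_table()
    with pytest.raises(EmptyInstrumentsError) as exc:
        select_instruments(stats, p_threshold=1e-12)
    assert exc.value.stage == "p_filter"


def test_select_instruments_weak_only_names_f_stage():
    stats = _stats([("rs1", "1", 100_000, "A", "G", 0.3, 0.001, 0.01, 0.9, 1e4)])
    with pytest.raises(EmptyInstrumentsError) as exc:
        select_instruments(stats, p_threshold=0.99)
    assert exc.value.stage == "f_filter"


def test_select_all_independent_reduces_to_p_filter():
    stats = _stats([
        ("rs1", "1", 100_000, "A", "G", 0.3, 0.10, 0.010, 1e-9, 1e4),
        ("rs2", "2", 100_000, "C", "T", 0.3, 0.09, 0.010, 1e-8, 1e4),
    ])
    ld = _block_ld(["rs1", "rs2"], 0.0, [])
    inst = select_instruments(stats, p_threshold=1e-6, ld=ld)
    assert inst.n_snps == 2 and inst.provenance["removed_clump"] == 0


def test_ld_matrix_validation_and_io(tmp_path):
    with pytest.raises(ValueError):
        LdMatrix(rsids=["a", "b"], r2=np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
    with pytest.raises(ValueError):
        LdMatrix(rsids=["a", "b"], r2=np.array([[1.0, 0.5], [0.5, 0.9]]))  # diag != 1
    ld = LdMatrix(rsids=["a", "b"], r2=np.array([[1.0, 0.25], [0.25, 1.0]]))
    f = tmp_path / "ld.tsv"
    ld.write_tsv(f)
    back = LdMatrix.read_tsv(f)
    assert back.rsids == ld.rsids
    assert back.get("a", "b") == pytest.approx(0.25)
    assert back.get("a", "zzz") is None
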