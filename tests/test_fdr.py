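import numpy as np
import pandas as pd
import pytest

import aneudose as ad
from conftest import make_table


def test_compensation_statistic_examples():
    rows = [
        ("g1", "XII", "s", 1, 0.585, 0.585),   # tracks dose -> 0
        ("g2", "XII", "s", 1, 1.0, 0.0),       # fully compensated -> -1
        ("g3", "XII", "s", 1, 0.1, -0.1),      # replicate 1: -0.2
        ("g3", "XII", "s", 2, 0.1, -0.3),      # replicate 2: -0.4
        ("g4", "XII", "s", 1, 0.5, np.nan),    # no complete pair -> excluded
    ]
    cs = ad.compensation_statistic(make_table(rows))
    assert cs.per_gene["g1"] == pytest.approx(0.0)
    assert cs.per_gene["g2"] == pytest.approx(-1.0)
    assert cs.per_gene["g3"] == pytest.approx(-0.3)
    assert "g4" not in cs.per_gene.index
    assert cs.n_excluded == 1


def test_effective_cutoff_reconstruction():
    stats = pd.Series(
        [-0.55, -0.45, -0.35, -0.35, -0.05, 0.15, 0.25],
        index=[f"g{i}" for i in range(7)],
    )
    flagged = {"g0", "g1", "g2"}  # everything below -0.3, plus half of one bin
    cut = ad.estimate_effective_cutoff(stats, flagged, width=0.1)
    assert cut.flag_probability([-0.58])[0] == 1.0
    assert cut.flag_probability([-0.42])[0] == 1.0
    assert cut.flag_probability([-0.31])[0] == 0.5   # 1 of 2 in [-0.4, -0.3)
    assert cut.flag_probability([0.17])[0] == 0.0
    assert cut.flag_probability([5.0])[0] == 0.0     # outside range -> 0
    with pytest.raises(ad.ValidationError):
        ad.estimate_effective_cutoff(stats, set())


def test_threshold_cutoff_is_step_function():
    cut = ad.EffectiveCutoff.from_threshold(-0.3)
    assert cut.flag_probability([-0.31, -0.29, 0.0]).tolist() == [1.0, 0.0, 0.0]


def test_combine_noise_arithmetic():
    assert ad.combine_noise(0.3, 0.1) == pytest.approx(0.31623, abs=1e-4)
    assert ad.combine_noise(0.0, 0.0) == 0.0
    assert ad.combine_noise(0.53, 0.10) == pytest.approx(0.53935, abs=1e-4)
    # dropping the DNA term never widens the null
    sig = np.linspace(0.3, 1.0, 10)
    assert (ad.combine_noise(sig, 0.0) <= ad.combine_noise(sig, 0.1)).all()
    with pytest.raises(ad.ValidationError):
        ad.combine_noise(-0.1, 0.1)


def test_permutation_preserves_column_multisets():
    rng = np.random.default_rng(0)
    V = pd.DataFrame(rng.normal(size=(50, 3)))
    order = np.argsort(rng.random(V.shape), axis=0)
    permuted = V.to_numpy()[order, np.arange(3)]
    for j in range(3):
        assert sorted(permuted[:, j]) == pytest.approx(sorted(V[j]))


def test_permutation_averaging_shrinks_spread(null_trisomy):
    """Per-gene means over r permuted replicates have ~1/sqrt(r) the spread
    of single-replicate values."""
    table, _ = null_trisomy
    cs = ad.compensation_statistic(table, chromosomes=["XII"])
    single_sd = cs.per_replicate.stack().std()
    mean_sd = cs.per_gene.std()
    assert mean_sd == pytest.approx(single_sd / np.sqrt(3), rel=0.15)


def test_permutation_fdr_null_near_100(null_trisomy):
    table, _ = null_trisomy
    cs = ad.compensation_statistic(table, chromosomes=["XII"])
    thr = cs.per_gene.quantile(0.1)
    cut = ad.estimate_effective_cutoff(cs.per_gene, (cs.per_gene <= thr).to_numpy())
    res = ad.permutation_fdr(cs.per_replicate, cut, B=400, seed=0)
    # conservative sampling band: 3 * 100 * sqrt((1-p)/observed) with p = obs/n
    tol = 3 * 100 * np.sqrt((1 - res.observed / len(cs.per_gene)) / res.observed)
    assert res.fdr_percent == pytest.approx(100.0, abs=tol)


def test_sampling_fdr_null_near_100(null_trisomy):
    table, _ = null_trisomy
    cs = ad.compensation_statistic(table, chromosomes=["XII"])
    thr = cs.per_gene.quantile(0.1)
    cut = ad.estimate_effective_cutoff(cs.per_gene, (cs.per_gene <= thr).to_numpy())
    sem = ad.per_gene_rna_sem(table, chromosomes=["XII"])
    res = ad.sampling_fdr(sem, 0.1 / np.sqrt(3), cut,
                          observed_count=50, B=400, seed=1)
    tol = 3 * 100 * np.sqrt((1 - 0.1) / 50)
    assert res.fdr_percent == pytest.approx(100.0, abs=tol)


def test_fdr_drops_when_true_compensation_present(small_layout):
    """Genuine compensation pulls the permutation FDR below the ~100% null.

    Between nonzero fractions the FDR is not monotone: permuted columns
    resample the compensated mode, so the null hit rate scales like
    3f(1-f) + f^2 relative to the observed f, giving ~28% at f=0.1 and
    ~72% at f=0.3 — both well under the f=0 level."""
    noise = ad.NoiseModel(0.05, (0.1, 0.1))
    cut = ad.EffectiveCutoff.from_threshold(-0.5)
    fdrs = []
    for f in (0.0, 0.1, 0.3):
        table, _ = ad.simulate_strain(
            small_layout, ad.KaryotypeSpec(2, {"XII": 4}), noise,
            ad.CompensationSpec(f, 1.0), seed=5,
        )
        cs = ad.compensation_statistic(table, chromosomes=["XII"])
        observed = int((cs.per_gene < -0.5).sum()) or None
        if observed is None:   # f=0: fall back to flagging the extreme tail
            thr = cs.per_gene.quantile(0.1)
            c = ad.estimate_effective_cutoff(cs.per_gene, (cs.per_gene <= thr).to_numpy())
            res = ad.permutation_fdr(cs.per_replicate, c, B=200, seed=6)
        else:
            res = ad.permutation_fdr(cs.per_replicate, cut, B=200, seed=6,
                                     observed_count=observed)
        fdrs.append(res.fdr_percent)
    assert fdrs[1] < fdrs[0] - 20
    assert fdrs[2] < fdrs[0] - 20


def test_fdr_reproducible_and_undefined_cases(null_trisomy):
    table, _ = null_trisomy
    cs = ad.compensation_statistic(table, chromosomes=["XII"])
    cut = ad.EffectiveCutoff.from_threshold(-0.3)
    a = ad.permutation_fdr(cs.per_replicate, cut, B=50, seed=7)
    b = ad.permutation_fdr(cs.per_replicate, cut, B=50, seed=7)
    assert np.array_equal(a.null_counts, b.null_counts)
    assert a.observed == b.observed
    with pytest.raises(ad.UndefinedFdrError):
        ad.permutation_fdr(cs.per_replicate, cut, B=10, seed=8, observed_count=0)
    with pytest.raises(ad.UndefinedFdrError):
        ad.sampling_fdr([0.3, 0.4], 0.1, cut, observed_count=0, B=10, seed=9)
    single = ad.sampling_fdr([0.3, 0.4], 0.1, cut, observed_count=1, B=1, seed=10)
    assert len(single.null_counts) == 1
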