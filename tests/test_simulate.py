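import numpy as np
import pandas as pd
import pytest

import aneudose as ad

ZERO_NOISE = ad.NoiseModel(sigma_dna=0.0, sigma_rna_range=(1e-12, 1e-12))


def rna_means(table):
    return table.df.groupby("chromosome")["rna_log2"].mean()


def dna_means(table):
    return table.df.groupby("chromosome")["dna_log2"].mean()


def test_genome_layout_examples():
    lay = ad.genome_layout({"VIII": 3})
    assert list(lay["gene_id"]) == ["g_VIII_0001", "g_VIII_0002", "g_VIII_0003"]
    assert set(lay["chromosome"]) == {"VIII"}

    default = ad.genome_layout()
    assert default["chromosome"].nunique() == 16
    assert 5500 <= len(default) <= 6500

    with pytest.raises(ad.ValidationError):
        ad.genome_layout({"I": 0})
    with pytest.raises(ad.ValidationError):
        ad.genome_layout({})


def test_noise_free_trisomy_hits_exact_dose():
    lay = ad.genome_layout({"XII": 20, "I": 20})
    table, truth = ad.simulate_strain(lay, ad.KaryotypeSpec(2, {"XII": 3}),
                                      ZERO_NOISE, seed=0)
    assert dna_means(table)["XII"] == pytest.approx(np.log2(3 / 2), abs=1e-9)
    assert rna_means(table)["XII"] == pytest.approx(np.log2(3 / 2), abs=1e-6)
    assert dna_means(table)["I"] == pytest.approx(0, abs=1e-9)
    assert truth.effective_copies == {"XII": 3.0, "I": 2.0}


def test_mixture_karyotype_effective_copy():
    spec = ad.KaryotypeSpec(2, {"V": [(0.5, 2), (0.5, 3)]})
    assert spec.effective_copy("V") == pytest.approx(2.5)
    lay = ad.genome_layout({"V": 30, "I": 10})
    table, _ = ad.simulate_strain(lay, spec, ZERO_NOISE, seed=0)
    assert dna_means(table)["V"] == pytest.approx(np.log2(2.5 / 2), abs=1e-9)


def test_full_compensation_zeroes_rna_only():
    lay = ad.genome_layout({"VIII": 10, "I": 10})
    comp = ad.CompensationSpec(fraction=0.3, depth=1.0)
    table, truth = ad.simulate_strain(lay, ad.KaryotypeSpec(2, {"VIII": 4}),
                                      ZERO_NOISE, comp, seed=0)
    assert len(truth.compensated_gene_ids) == 3
    per_gene = table.df.groupby("gene_id")[["dna_log2", "rna_log2"]].mean()
    on_viii = per_gene.loc[[g for g in per_gene.index if "VIII" in g]]
    assert np.allclose(on_viii["dna_log2"], 1.0, atol=1e-9)
    comp_rna = on_viii.loc[sorted(truth.compensated_gene_ids), "rna_log2"]
    rest_rna = on_viii.drop(index=truth.compensated_gene_ids)["rna_log2"]
    assert np.allclose(comp_rna, 0.0, atol=1e-6)
    assert np.allclose(rest_rna, 1.0, atol=1e-6)
    # compensated genes never land on euploid chromosomes
    assert all("VIII" in g for g in truth.compensated_gene_ids)


def test_series_shares_truth_and_scales_means():
    lay = ad.genome_layout({"VIII": 12, "I": 8})
    comp = ad.CompensationSpec(fraction=0.5, depth=1.0)
    sims = ad.simulate_ploidy_series(lay, "VIII", [2, 3, 4], ZERO_NOISE, comp, seed=0)
    means = [rna_means(t)["VIII"] for t, _ in sims]
    dna = [dna_means(t)["VIII"] for t, _ in sims]
    assert dna == pytest.approx([0.0, np.log2(1.5), 1.0], abs=1e-9)
    # with half the genes fully compensated, RNA means sit at half the dose
    assert means == pytest.approx([0.0, np.log2(1.5) / 2, 0.5], abs=1e-6)
    comp_sets = {s[1].compensated_gene_ids for s in sims[1:]}
    assert len(comp_sets) == 1  # shared across the aneuploid levels


def test_fixed_seed_is_bit_reproducible(small_layout):
    noise = ad.NoiseModel(0.1, (0.4, 0.8))
    karyo = ad.KaryotypeSpec(2, {"XII": 3})
    a, _ = ad.simulate_strain(small_layout, karyo, noise, seed=7)
    b, _ = ad.simulate_strain(small_layout, karyo, noise, seed=7)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_dna_mean_converges_and_rna_disperses_more(null_trisomy):
    table, truth = null_trisomy
    n = (table.df["chromosome"] == "XII").sum() // 3
    dna_mean = dna_means(table)["XII"]
    assert abs(dna_mean - np.log2(1.5)) < 3 * 0.1 / np.sqrt(n)
    sds = table.df.groupby("chromosome")[["dna_log2", "rna_log2"]].std()
    assert (sds["rna_log2"] > sds["dna_log2"]).all()


def test_compensated_fraction_skews_rna_left(small_layout):
    """With f=0 the replicate-averaged RNA distribution on the amplified
    chromosome is symmetric; with f=0.3, d=1 its sample skewness is negative
    in nearly every realization (population value ~ -0.23 at this noise)."""
    noise = ad.NoiseModel(0.1, (0.55, 0.55))
    karyo = ad.KaryotypeSpec(2, {"XII": 3})
    xii = lambda t: t.df[t.df["chromosome"] == "XII"].groupby("gene_id")["rna_log2"].mean()
    t0, _ = ad.simulate_strain(small_layout, karyo, noise, seed=11)
    assert abs(ad.moments(xii(t0)).skewness) < 0.3
    negatives = 0
    for seed in range(20):
        t3, _ = ad.simulate_strain(small_layout, karyo, noise,
                                   ad.CompensationSpec(0.3, 1.0), seed=seed)
        negatives += ad.moments(xii(t3)).skewness < 0
    # population skew -0.23 vs sampling SE ~0.11 at n=500 -> P(neg) ~ 0.98
    assert negatives >= 16


def test_noise_model_rejects_dna_noise_above_rna():
    with pytest.raises(ad.ValidationError):
        ad.NoiseModel(sigma_dna=0.5, sigma_rna_range=(0.4, 0.8))


def test_karyotype_spec_validates_mixtures():
    with pytest.raises(ad.ValidationError, match="sum to 1"):
        ad.KaryotypeSpec(2, {"I": [(0.5, 2), (0.4, 3)]})
    with pytest.raises(ad.ValidationError):
        ad.KaryotypeSpec(2, {"I": -1})


def test_average_dna_switch_makes_replicates_identical(small_layout):
    noise = ad.NoiseModel(0.1, (0.4, 0.8))
    table, _ = ad.simulate_strain(small_layout, ad.KaryotypeSpec(2, {"XII": 3}),
                                  noise, seed=5, average_dna=True)
    wide = table.df.pivot_table(index="gene_id", columns="replicate",
                                values="dna_log2")
    assert np.allclose(wide.var(axis=1), 0.0)
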