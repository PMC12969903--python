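import numpy as np
import pandas as pd
import pytest

from pangsv import (
    PhasedPanel,
    SimConfig,
    estimate_effects,
    find_tag_haplotype,
    ld_r2,
    simulate_haplotypes,
    simulate_reference,
    simulate_array_and_phenotypes,
)


def _panel(haps: np.ndarray) -> PhasedPanel:
    n, _, m = haps.shape
    markers = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, m + 1) * 100, "id": [f"M{i}" for i in range(m)]}
    )
    return PhasedPanel(
        animals=[f"A{i}" for i in range(n)], markers=markers, haplotypes=haps.astype(np.int8)
    )


def test_unique_case_haplotype_is_found_with_zero_controls():
    rng = np.random.default_rng(0)
    haps = rng.integers(0, 2, size=(20, 2, 9))
    tag = np.array([1, 0, 1, 1, 0])
    cases = [f"A{i}" for i in range(5)]
    for i in range(5):
        haps[i, 0, 2:7] = tag
    # make sure no control haplotype carries the tag by accident
    for i in range(5, 20):
        for h in (0, 1):
            if (haps[i, h, 2:7] == tag).all():
                haps[i, h, 2] = 1 - haps[i, h, 2]
    for i in range(5):
        if (haps[i, 1, 2:7] == tag).all():
            haps[i, 1, 2] = 1 - haps[i, 1, 2]
    panel = _panel(haps)
    controls = [f"A{i}" for i in range(5, 20)]
    result = find_tag_haplotype(panel, cases, controls, window_bounds=(5, 5))
    assert result.found
    assert (result.window_start, result.window_end) == (2, 6)
    assert result.allele_string == "10110"
    assert result.control_carriers == 0
    assert result.r2 == pytest.approx(1.0)
    copies = result.genotype_class
    assert all(copies[a] >= 1 for a in cases)


def test_no_shared_string_returns_not_found():
    haps = np.zeros((4, 2, 6), dtype=np.int8)
    haps[0, :, :] = 1  # case 0 haplotypes all-ones, case 1 all-zeros
    panel = _panel(haps)
    result = find_tag_haplotype(
        panel, ["A0", "A1"], ["A2", "A3"], window_bounds=(2, 6)
    )
    assert not result.found


def test_cases_and_controls_must_be_disjoint_and_nonempty():
    haps = np.zeros((4, 2, 6), dtype=np.int8)
    panel = _panel(haps)
    with pytest.raises(ValueError):
        find_tag_haplotype(panel, ["A0"], ["A0", "A1"])
    with pytest.raises(ValueError):
        find_tag_haplotype(panel, [], ["A1"])


def _brute_force_tag(panel, cases, controls, bounds):
    """Independent exhaustive search mirroring the two filters, written
    over explicit allele strings."""
    m = panel.n_markers
    idx = {a: i for i, a in enumerate(panel.animals)}
    best = None
    for width in range(bounds[0], min(bounds[1], m) + 1):
        for start in range(0, m - width + 1):
            window = panel.haplotypes[:, :, start : start + width]
            strings = [
                ["".join(map(str, window[idx[a], h])) for h in (0, 1)]
                for a in panel.animals
            ]
            universe = {s for pair in strings for s in pair}
            for cand in sorted(universe):
                if all(cand in strings[idx[a]] for a in cases):
                    n_controls = sum(cand in strings[idx[a]] for a in controls)
                    key = (n_controls, width, start, cand)
                    if best is None or key < best:
                        best = key
    return best


def test_search_matches_exhaustive_enumeration_on_small_panels():
    rng = np.random.default_rng(3)
    for trial in range(8):
        n, m = 12, int(rng.integers(6, 13))
        haps = rng.integers(0, 2, size=(n, 2, m))
        panel = _panel(haps)
        cases = [f"A{i}" for i in range(3)]
        controls = [f"A{i}" for i in range(3, n)]
        bounds = (2, 6)
        expected = _brute_force_tag(panel, cases, controls, bounds)
        result = find_tag_haplotype(panel, cases, controls, bounds)
        if expected is None:
            assert not result.found
        else:
            n_controls, width, start, cand = expected
            assert result.found
            assert result.control_carriers == n_controls
            assert (result.window_start, result.window_end) == (start, start + width - 1)
            assert result.allele_string == cand


def test_planted_tag_recovered_from_simulation(bundle):
    truth_tag = bundle.truth.tag_haplotype
    geno = bundle.nrui_genotypes
    rng = np.random.default_rng(5)
    cases = sorted(rng.choice(geno.loc[geno["case"], "animal"], size=40, replace=False))
    controls = sorted(rng.choice(geno.loc[~geno["case"], "animal"], size=40, replace=False))
    center = (truth_tag.window_start + truth_tag.window_end) // 2
    result = find_tag_haplotype(
        bundle.marker_panel, cases, controls, (2, 10), center_index=center
    )
    assert result.found
    assert result.allele_string in truth_tag.allele_string
    assert result.window_start >= truth_tag.window_start - 5
    assert result.control_carriers == 0
    # genotype classes derived from the tag equal the true NRUI genotypes
    truth_classes = geno.set_index("animal")["genotype"]
    sub = result.genotype_class.loc[truth_classes.index]
    frac_equal = (sub == truth_classes).mean()
    assert frac_equal > 0.999


def test_ld_r2_reference_values():
    a = np.array([1, 1, 0, 0, 1, 0])
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert ld_r2(a, 1 - a) == pytest.approx(1.0)  # r = -1
    # 2x2 table n11=40, n10=10, n01=10, n00=40 -> r = 0.6, r^2 = 0.36
    x = np.repeat([1, 1, 0, 0], [40, 10, 10, 40])
    y = np.repeat([1, 0, 1, 0], [40, 10, 10, 40])
    assert ld_r2(x, y) == pytest.approx(0.36)
    assert ld_r2(y, x) == pytest.approx(0.36)
    # invariance to 0/1 label swap
    assert ld_r2(1 - x, y) == pytest.approx(0.36)


def test_ld_r2_constant_vector_is_nan():
    assert np.isnan(ld_r2(np.ones(5), np.array([0, 1, 0, 1, 0])))


def _simulate_effects(seed, **cfg_kwargs):
    cfg = SimConfig(seed=seed, n_markers=8, tag_window_size=5, **cfg_kwargs)
    ref = simulate_reference(cfg)
    _, truth = simulate_haplotypes(ref, cfg)
    _, geno, pheno = simulate_array_and_phenotypes(truth, cfg)
    eff = estimate_effects(pheno, geno.set_index("animal")["genotype"], cfg.trait_sd)
    return eff.iloc[0]


def test_effect_estimates_recover_planted_additive_effects():
    row = _simulate_effects(seed=29)
    assert row["contrast_het_gsd"] == pytest.approx(0.25, abs=0.05)
    assert row["contrast_hom_gsd"] == pytest.approx(0.50, abs=0.05)
    assert row["p_adj_het"] < 1e-6 and row["p_adj_hom"] < 1e-6


def test_effect_estimates_under_null_are_small():
    row = _simulate_effects(seed=31, effect_gsd=(0.0, 0.0))
    assert abs(row["contrast_het_gsd"]) < 0.05
    assert abs(row["contrast_hom_gsd"]) < 0.05


def test_balanced_year_effects_leave_contrasts_invariant():
    strong = _simulate_effects(seed=37, year_sd=2.0)
    none = _simulate_effects(seed=37, year_sd=0.0)
    assert strong["contrast_het_gsd"] == pytest.approx(none["contrast_het_gsd"], abs=0.02)
    assert strong["contrast_hom_gsd"] == pytest.approx(none["contrast_hom_gsd"], abs=0.02)


def test_small_class_is_reported_missing():
    rng = np.random.default_rng(7)
    n = 500
    animals = [f"A{i}" for i in range(n)]
    classes = pd.Series([0] * (n - 5) + [1] * 5, index=animals)
    pheno = pd.DataFrame(
        {
            "animal": animals,
            "year": rng.choice([2019, 2020], size=n),
            "trait": "stature",
            "value": rng.normal(size=n),
        }
    )
    eff = estimate_effects(pheno, classes, 1.0, min_class_size=30)
    assert np.isnan(eff.loc[0, "contrast_het_gsd"])
    assert np.isnan(eff.loc[0, "contrast_hom_gsd"])


def test_phased_panel_tsv_round_trip(tmp_path, bundle):
    panel = bundle.marker_panel
    # keep it quick: first 50 animals
    small = PhasedPanel(
        animals=panel.animals[:50],
        markers=panel.markers,
        haplotypes=panel.haplotypes[:50],
    )
    path = tmp_path / "markers.tsv"
    small.to_matrix_tsv(str(path))
    back = PhasedPanel.from_matrix_tsv(str(path), markers=panel.markers)
    assert back.animals == small.animals
    np.testing.assert_array_equal(back.haplotypes, small.haplotypes)
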