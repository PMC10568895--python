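"""Generators: determinism, tree consistency, depth scaling, scenario
behaviour and the end-to-end fixture bundle."""

import json

import numpy as np
import pytest
from scipy import stats

from ypanel.calling import CallingThresholds, call_sample
from ypanel.inference import infer_haplogroup
from ypanel.panel import build_tree, parse_haplogroup_name, read_panel
from ypanel.popstats import multiplicity_summary
from ypanel.synthdata import (
    DegradationScenario,
    DepthModel,
    DilutionScenario,
    InhibitionScenario,
    MixtureScenario,
    _expected_called,
    bundle_checksums,
    detection_probabilities,
    generate_panel_fixture,
    path_derived_markers,
    reference_pedigrees,
    simulate_pedigree,
    simulate_population,
    simulate_readcounts,
    write_fixture_bundle,
    write_truth_vcf,
)


class TestPanelFixture:
    def test_requested_size_and_buildable(self):
        fx = generate_panel_fixture(n_markers=20, clade_mix={"O": 0.6, "C": 0.2, "Q": 0.2}, seed=1)
        assert len(fx.markers) == 20
        assert len(fx.tree) >= 3
        clades = {parse_haplogroup_name(m.haplogroup).clade for m in fx.markers}
        assert clades == {"O", "C", "Q"}

    def test_seed_determinism_byte_identical(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        generate_panel_fixture(n_markers=50, seed=7).write(a)
        generate_panel_fixture(n_markers=50, seed=7).write(b)
        assert a.read_bytes() == b.read_bytes()
        c = tmp_path / "c.tsv"
        generate_panel_fixture(n_markers=50, seed=8).write(c)
        assert a.read_bytes() != c.read_bytes()

    def test_amplicon_lengths_within_panel_geometry(self):
        fx = generate_panel_fixture(n_markers=2000, seed=2)
        lengths = [m.amplicon_length for m in fx.markers]
        assert min(lengths) >= 120 and max(lengths) <= 273
        assert abs(float(np.mean(lengths)) - 200) < 3

    def test_negative_clade_weight_rejected(self):
        with pytest.raises(ValueError):
            generate_panel_fixture(n_markers=5, clade_mix={"O": -1.0}, seed=0)

    def test_prefix_families_connected(self):
        fx = generate_panel_fixture(n_markers=100, seed=3)
        for node in fx.tree.nodes():
            parent = node.parent
            if not parent.is_root:
                assert parent.label.is_prefix_of(node.label)


class TestPopulationSim:
    def test_truth_states_are_tree_consistent(self, fixture_panel):
        leaves = sorted(n.text for n in fixture_panel.tree.nodes() if not n.children)
        truth = simulate_population(fixture_panel.tree, {lab: 1.0 for lab in leaves}, 20, seed=3)
        for rec in truth:
            assert rec.derived_markers == path_derived_markers(
                fixture_panel.tree, rec.haplogroup
            )

    def test_spectrum_conservation(self, fixture_panel):
        leaves = sorted(n.text for n in fixture_panel.tree.nodes() if not n.children)
        truth = simulate_population(fixture_panel.tree, {lab: 1.0 for lab in leaves}, 183, seed=4)
        spectrum = multiplicity_summary([t.haplogroup for t in truth])
        assert spectrum.n == 183

    def test_concentrated_weights_identical_samples(self, fixture_panel):
        lab = sorted(n.text for n in fixture_panel.tree.nodes())[0]
        truth = simulate_population(fixture_panel.tree, {lab: 1.0}, 5, seed=5)
        assert {t.haplogroup for t in truth} == {lab}

    def test_unknown_weight_label_rejected(self, fixture_panel):
        with pytest.raises(KeyError):
            simulate_population(fixture_panel.tree, {"Z9z9": 1.0}, 5, seed=0)

    def test_empirical_frequencies_within_three_se(self, fixture_panel):
        labels = sorted(n.text for n in fixture_panel.tree.nodes())[:4]
        weights = dict(zip(labels, (0.4, 0.3, 0.2, 0.1)))
        n = 2000
        truth = simulate_population(fixture_panel.tree, weights, n, seed=6)
        from collections import Counter

        freq = Counter(t.haplogroup for t in truth)
        for lab, w in weights.items():
            se = np.sqrt(w * (1 - w) / n)
            assert abs(freq[lab] / n - w) < 3 * se


class TestPedigreeSim:
    def test_zero_mutation_rate_clones_founder(self, fixture_panel):
        ped = reference_pedigrees()
        founder_lab = sorted(n.text for n in fixture_panel.tree.nodes())[-1]
        truth = simulate_pedigree(fixture_panel.tree, founder_lab, ped, 0.0, seed=1)
        expected = path_derived_markers(fixture_panel.tree, founder_lab)
        assert all(t.derived_markers == expected for t in truth.values())

    def test_rate_one_flips_every_locus_each_meiosis(self, fixture_panel):
        ped = reference_pedigrees()
        founder_lab = sorted(n.text for n in fixture_panel.tree.nodes())[0]
        truth = simulate_pedigree(fixture_panel.tree, founder_lab, ped, 1.0, seed=2)
        n_loci = len(fixture_panel.markers)
        for father, son in ped.graph.edges:
            diff = truth[father].derived_markers ^ truth[son].derived_markers
            assert len(diff) == n_loci

    def test_mutation_count_within_poisson_interval(self):
        """639 loci x 23 sampled meioses at rate 1e-3: the observed
        parent-offspring discordance count lies in the Poisson 99%
        interval around 14.7."""
        from ypanel.popstats import pedigree_concordance

        fx = generate_panel_fixture(n_markers=639, seed=13)
        ped = reference_pedigrees()
        founder_lab = sorted(n.text for n in fx.tree.nodes())[0]
        truth = simulate_pedigree(fx.tree, founder_lab, ped, mutation_rate=1e-3, seed=3)
        names = [m.name for m in fx.markers]
        profiles = {n: truth[n].states(names) for n in ped.sampled}
        rep = pedigree_concordance(profiles, ped)
        mean = 639 * 23 * 1e-3
        lo, hi = stats.poisson.ppf([0.005, 0.995], mean)
        assert lo <= rep.mutation_events <= hi

    def test_founder_label_must_be_in_tree(self, fixture_panel):
        with pytest.raises(KeyError):
            simulate_pedigree(fixture_panel.tree, "Z9", reference_pedigrees(), 0.0, seed=0)


@pytest.fixture(scope="module")
def setup():
    fx = generate_panel_fixture(n_markers=639, seed=11)
    leaves = sorted(n.text for n in fx.tree.nodes() if not n.children)
    truth = simulate_population(fx.tree, {leaves[0]: 1.0}, n=3, seed=1)
    return fx, truth


class TestReadcounts:
    def test_full_input_calls_whole_panel(self, setup):
        fx, truth = setup
        counts = simulate_readcounts(truth, fx.markers, DepthModel(), seed=2)
        for sample_counts in counts.values():
            assert call_sample(sample_counts, fx.markers).called_count == 639

    def test_reads_match_truth_state(self, setup):
        fx, truth = setup
        counts = simulate_readcounts(truth, fx.markers, DepthModel(), seed=2)
        derived = truth[0].derived_markers
        for c in counts[truth[0].sample_id]:
            if c.marker_name in derived:
                assert c.ancestral_reads == 0
            else:
                assert c.derived_reads == 0

    def test_zero_survival_drops_everything(self, setup):
        fx, truth = setup
        counts = simulate_readcounts(
            truth, fx.markers, DepthModel(), DilutionScenario(mass_ng=0.0), seed=3
        )
        for sample_counts in counts.values():
            assert call_sample(sample_counts, fx.markers).called_count == 0

    def test_seed_determinism(self, setup):
        fx, truth = setup
        a = simulate_readcounts(truth, fx.markers, DepthModel(), seed=5)
        b = simulate_readcounts(truth, fx.markers, DepthModel(), seed=5)
        assert a == b

    def test_depth_scales_linearly_with_mass(self, setup):
        """Mean depth against input mass has unit slope on a log-log scale."""
        fx, truth = setup
        model = DepthModel()
        masses = [0.06, 0.25, 1.0, 2.0]
        means = []
        for mass in masses:
            counts = simulate_readcounts(
                truth[:1], fx.markers, model, DilutionScenario(mass_ng=mass), seed=7
            )
            depths = [c.depth for c in counts[truth[0].sample_id]]
            means.append(np.mean(depths))
        slope = np.polyfit(np.log(masses), np.log(means), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_degradation_calibration_reproduces_anchor_yield(self, setup):
        """With the length scale calibrated to the published degraded-DNA
        anchor (529 of 639 loci at DI 11.76), simulated called-locus
        counts fall within 3 SD of the expectation."""
        fx, truth = setup
        model = DepthModel()
        scen = DegradationScenario.calibrated(fx.markers, model, di=11.76, target_called=529.0)
        thresholds = CallingThresholds()
        expected = _expected_called(fx.markers, model, scen, thresholds)
        assert expected == pytest.approx(529.0, abs=0.1)
        p = detection_probabilities(fx.markers, model, scen, thresholds)
        sd = float(np.sqrt(np.sum(p * (1 - p))))
        counts = simulate_readcounts(truth, fx.markers, model, scen, seed=8)
        for sample_counts in counts.values():
            called = call_sample(sample_counts, fx.markers, thresholds).called_count
            assert abs(called - expected) <= 3 * sd

    def test_degradation_monotone_in_di_and_length(self, setup):
        fx, _ = setup
        mild = DegradationScenario(di=2.0, length_scale=110.0)
        harsh = DegradationScenario(di=30.0, length_scale=110.0)
        assert harsh.survival(200) < mild.survival(200)
        assert mild.survival(273) < mild.survival(120)
        with pytest.raises(ValueError):
            DegradationScenario(di=0.5)

    def test_inhibition_retention_lookup_and_interpolation(self):
        scen = InhibitionScenario("tannic_acid", 50.0)
        assert scen.retention() == 1.0
        mid = InhibitionScenario("tannic_acid", 125.0).retention()
        assert (
            InhibitionScenario("tannic_acid", 150.0).retention()
            < mid
            < InhibitionScenario("tannic_acid", 100.0).retention()
        )
        with pytest.raises(KeyError):
            InhibitionScenario("soap", 1.0)

    def test_mixture_background_never_carries_derived_alleles(self, setup):
        fx, truth = setup
        scen = MixtureScenario(male_mass_ng=1.0, female_mass_ng=100.0)
        counts = simulate_readcounts(truth, fx.markers, DepthModel(), scen, seed=9)
        derived = truth[0].derived_markers
        for c in counts[truth[0].sample_id]:
            if c.marker_name not in derived:
                assert c.derived_reads == 0
        # female background present as off-target reads somewhere
        assert any(c.other_reads > 0 for c in counts[truth[0].sample_id])


class TestVcfRoundTrip:
    def test_write_then_extract_reproduces_truth(self, tmp_path, fixture_panel):
        from ypanel.calling import extract_panel_genotypes_from_vcf

        leaves = sorted(n.text for n in fixture_panel.tree.nodes() if not n.children)
        rec = simulate_population(fixture_panel.tree, {leaves[-1]: 1.0}, 1, seed=3)[0]
        path = write_truth_vcf(rec, fixture_panel.markers, tmp_path / "s.vcf")
        profile = extract_panel_genotypes_from_vcf(path, fixture_panel.markers)
        states = profile.states()
        for m in fixture_panel.markers:
            expected = "DERIVED" if m.name in rec.derived_markers else "ANCESTRAL"
            assert states[m.name].value == expected

    def test_contig_alias_y_normalised(self, tmp_path, fixture_panel):
        from ypanel.calling import extract_panel_genotypes_from_vcf

        leaves = sorted(n.text for n in fixture_panel.tree.nodes() if not n.children)
        rec = simulate_population(fixture_panel.tree, {leaves[0]: 1.0}, 1, seed=4)[0]
        path = write_truth_vcf(rec, fixture_panel.markers, tmp_path / "s.vcf", contig="Y")
        profile = extract_panel_genotypes_from_vcf(path, fixture_panel.markers)
        assert profile.called_count == len(fixture_panel.markers)

    def test_positions_absent_from_vcf_are_nocalls(self, tmp_path, fixture_panel):
        from ypanel.calling import extract_panel_genotypes_from_vcf

        leaves = sorted(n.text for n in fixture_panel.tree.nodes() if not n.children)
        rec = simulate_population(fixture_panel.tree, {leaves[0]: 1.0}, 1, seed=5)[0]
        subset = fixture_panel.markers[: len(fixture_panel.markers) // 2]
        path = write_truth_vcf(rec, subset, tmp_path / "s.vcf")
        profile = extract_panel_genotypes_from_vcf(path, fixture_panel.markers)
        absent = {m.name for m in fixture_panel.markers} - {m.name for m in subset}
        assert all(not profile.calls[name].is_called for name in absent)

    def test_round_trip_inference_consistent(self, tmp_path, fixture_panel):
        from ypanel.calling import extract_panel_genotypes_from_vcf

        leaves = sorted(n.text for n in fixture_panel.tree.nodes() if not n.children)
        rec = simulate_population(fixture_panel.tree, {leaves[2]: 1.0}, 1, seed=6)[0]
        path = write_truth_vcf(rec, fixture_panel.markers, tmp_path / "s.vcf")
        profile = extract_panel_genotypes_from_vcf(path, fixture_panel.markers)
        assert infer_haplogroup(profile, fixture_panel.tree).terminal == rec.haplogroup


class TestFixtureBundle:
    def test_end_to_end_recovery_and_determinism(self, tmp_path):
        paths = write_fixture_bundle(tmp_path / "b1", seed=0)
        markers = read_panel(paths["panel"])
        tree = build_tree(markers)
        from ypanel.calling import read_counts_tsv

        truth = json.loads(paths["truth"].read_text())
        counts = read_counts_tsv(paths["counts"])
        for sample, sample_counts in counts.items():
            profile = call_sample(sample_counts, markers, sample_id=sample)
            a = infer_haplogroup(profile, tree)
            assert a.terminal == truth["cohort"][sample]
        paths2 = write_fixture_bundle(tmp_path / "b2", seed=0)
        assert bundle_checksums(paths) == bundle_checksums(paths2)

    def test_existing_nonempty_dir_needs_force(self, tmp_path):
        out = tmp_path / "bundle"
        write_fixture_bundle(out, seed=1)
        with pytest.raises(FileExistsError):
            write_fixture_bundle(out, seed=1)
        write_fixture_bundle(out, seed=1, force=True)
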