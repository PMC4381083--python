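import numpy as np
import pytest

from ribotradeoff.folding import (
    PAIR_ENERGY_GC,
    NussinovEngine,
    ViennaEngine,
    get_engine,
)
from ribotradeoff.sequence_io import CodingSequence
from ribotradeoff.structure import (
    StructureProfile,
    ThresholdRule,
    extract_regions,
    load_structure_scores,
    sliding_window_mfe,
)


def pars_profile(values, gene_id="g"):
    values = np.asarray(values, dtype=float)
    return StructureProfile(
        gene_id=gene_id, kind="pars", values=values, defined=~np.isnan(values)
    )


def brute_force_regions(labels, min_len):
    """Independent maximal-run scan: extend each qualifying start greedily."""
    out = []
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == 0:
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if j - i >= min_len:
            out.append((i, j, "high" if labels[i] == 1 else "low"))
        i = j
    return out


def labels_from_pars(values):
    out = []
    for v in values:
        if np.isnan(v):
            out.append(0)
        else:
            out.append(1 if v > 0 else -1)
    return out


class TestThresholdRule:
    def test_mfe_rule_needs_gap(self):
        with pytest.raises(ValueError):
            ThresholdRule(kind="mfe", high_cut=-20, low_cut=-35)

    def test_pars_zero_is_low(self):
        profile = pars_profile([0.0] * 25)
        regions = extract_regions(profile, ThresholdRule.pars_default(20))
        assert len(regions) == 1 and regions[0].klass == "low"

    def test_mfe_unclassified_band(self):
        profile = StructureProfile(
            gene_id="g", kind="mfe", values=np.full(50, -25.0), defined=np.ones(50, bool)
        )
        assert extract_regions(profile, ThresholdRule.mfe_default(20)) == []

    def test_kind_mismatch(self):
        with pytest.raises(ValueError):
            extract_regions(pars_profile([1.0] * 30), ThresholdRule.mfe_default())


class TestExtractRegions:
    def test_single_high_run_with_short_low(self):
        values = [+1.0] * 25 + [-1.0] * 10 + [+1.0] * 5
        regions = extract_regions(pars_profile(values), ThresholdRule.pars_default(20))
        assert [(r.start_nt, r.end_nt, r.klass) for r in regions] == [(0, 25, "high")]

    def test_all_undefined_empty(self):
        assert (
            extract_regions(pars_profile([np.nan] * 100), ThresholdRule.pars_default())
            == []
        )

    def test_runs_are_maximal_not_split(self):
        regions = extract_regions(
            pars_profile([1.0] * 25), ThresholdRule.pars_default(20)
        )
        assert [(r.start_nt, r.end_nt) for r in regions] == [(0, 25)]

    def test_undefined_breaks_runs(self):
        values = [1.0] * 15 + [np.nan] + [1.0] * 15
        assert (
            extract_regions(pars_profile(values), ThresholdRule.pars_default(10))
            == extract_regions(pars_profile(values), ThresholdRule.pars_default(10))
        )
        regions = extract_regions(pars_profile(values), ThresholdRule.pars_default(10))
        assert [(r.start_nt, r.end_nt) for r in regions] == [(0, 15), (16, 31)]

    def test_matches_brute_force_oracle(self, rng):
        rule = ThresholdRule.pars_default(5)
        for _ in range(300):
            n = int(rng.integers(1, 200))
            values = rng.normal(0, 1, n)
            values[rng.random(n) < 0.1] = np.nan
            got = [
                (r.start_nt, r.end_nt, r.klass)
                for r in extract_regions(pars_profile(values), rule)
            ]
            assert got == brute_force_regions(labels_from_pars(values), 5)

    def test_min_len_nesting(self, rng):
        """Raising R_l only removes regions, never alters surviving ones."""
        values = rng.normal(0, 1, 500)
        sets = {
            rl: {
                (r.start_nt, r.end_nt, r.klass)
                for r in extract_regions(
                    pars_profile(values), ThresholdRule.pars_default(rl)
                )
            }
            for rl in (10, 20, 30)
        }
        assert sets[30] <= sets[20] <= sets[10]

    def test_high_low_regions_never_overlap(self, rng):
        values = rng.normal(0, 1, 300)
        regions = extract_regions(pars_profile(values), ThresholdRule.pars_default(5))
        covered = {}
        for r in regions:
            for pos in range(r.start_nt, r.end_nt):
                assert pos not in covered
                covered[pos] = r.klass


class TestSlidingWindowMfe:
    def test_poly_a_is_zero(self):
        cds = CodingSequence(id="a", seq="A" * 201)
        profile = sliding_window_mfe(cds, 101)
        assert np.all(profile.values[profile.defined] == 0.0)

    def test_edges_undefined(self):
        cds = CodingSequence(id="g", seq="ACG" * 67)  # 201 nt
        profile = sliding_window_mfe(cds, 101)
        assert not profile.defined[:50].any() and not profile.defined[-50:].any()
        assert profile.defined[50:-50].all()

    def test_short_sequence_all_undefined(self):
        cds = CodingSequence(id="s", seq="ACG" * 10)
        assert not sliding_window_mfe(cds, 101).defined.any()

    def test_perfect_hairpin_energy(self):
        # 48-bp G:C stem with a 5-nt loop fills one 101-nt window exactly;
        # the optimal nested pairing is the full stem.
        hairpin = "G" * 48 + "AAAAA" + "C" * 48
        cds = CodingSequence(id="h", seq=hairpin + "A")  # pad to frame (102 nt)
        engine = NussinovEngine()
        assert engine.fold_mfe(hairpin) == pytest.approx(-48 * PAIR_ENERGY_GC)

    def test_banded_profile_matches_per_window(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        cds = CodingSequence(id="g", seq=seq)
        engine = NussinovEngine()
        profile = sliding_window_mfe(cds, 101, engine)
        for center in [50, 70, 99]:
            direct = engine.fold_mfe(seq[center - 50 : center + 51])
            assert profile.values[center] == pytest.approx(direct)

    def test_permutation_sensitive(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        shuffled = "".join(rng.permutation(list(seq)))
        p1 = sliding_window_mfe(CodingSequence(id="a", seq=seq), 101)
        p2 = sliding_window_mfe(CodingSequence(id="b", seq=shuffled), 101)
        assert not np.allclose(p1.values[p1.defined], p2.values[p2.defined])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_mfe(CodingSequence(id="g", seq="ACG" * 40), 100)

    def test_vienna_engine_if_available(self):
        pytest.importorskip("RNA")
        engine = get_engine("vienna")
        assert isinstance(engine, ViennaEngine)
        # a strong hairpin folds, an oligo-A does not
        assert engine.fold_mfe("G" * 20 + "AAAAA" + "C" * 20) < -20
        assert engine.fold_mfe("A" * 45) == 0.0


class TestLoadScores:
    def test_offset_realignment(self, tmp_path):
        cds = CodingSequence(
            id="geneX", seq="ACG" * 40, trimmed=True, offset_nt=51
        )
        path = tmp_path / "scores.tsv"
        path.write_text(
            "gene_id\tposition\tscore\n"
            "geneX\t51\t1.7\n"  # first trimmed position
            "geneX\t10\t9.9\n"  # inside trimmed-away 5' region: dropped
            "geneY\t51\t0.1\n"  # unknown gene: skipped
        )
        (profile,) = load_structure_scores(path, [cds], 51)
        assert profile.values[0] == pytest.approx(1.7)
        assert profile.defined.sum() == 1

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tposition\tscore\ng\t51\t\n")
        cds = CodingSequence(id="g", seq="ACG" * 40, trimmed=True, offset_nt=51)
        with pytest.raises(ValueError, match="line 2"):
            load_structure_scores(path, [cds], 51)

    def test_round_trip_synthetic_scores(self, tmp_path, pars_genome, pars_trimmed):
        path = tmp_path / "scores.tsv"
        pars_genome.scores.to_csv(path, sep="\t", index=False)
        profiles = load_structure_scores(path, pars_trimmed, 51)
        by_id = {p.gene_id: p for p in profiles}
        for cds in pars_trimmed:
            profile = by_id[cds.id]
            # every core position was scored, so the profile is fully defined
            assert profile.defined.all()
            assert len(profile) == len(cds.seq)
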