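"""Logo information content, composition, architectures, co-occurrence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarity_lapse import (
    AlignmentSpec,
    CooccurrenceTable,
    DomainHit,
    PatternSpec,
    alignment_logo,
    column_information,
    composition_by_class,
    generate_alignment,
    generate_presence_absence,
    query_cooccurrence,
    resolve_architecture,
    tabulate_cooccurrence,
)
from polarity_lapse.seq_features import AMINO_ACIDS, DEFAULT_CLASS_MAP
from polarity_lapse.synthetic import conserved_region_profiles

LOG2_20 = math.log2(20)


class TestInformationContent:
    def test_invariant_column_without_correction(self):
        prof = column_information("W" * 50, correct_small_sample=False)
        assert prof.information == pytest.approx(LOG2_20)
        assert prof.letter_heights["W"] == pytest.approx(LOG2_20)

    def test_uniform_column_zero_bits(self):
        prof = column_information(AMINO_ACIDS, correct_small_sample=False)
        assert prof.information == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_correction_closed_form(self):
        # n=20 identical residues: R = log2(20) - 19/(40·ln2)
        prof = column_information("W" * 20, correct_small_sample=True)
        assert prof.information == pytest.approx(LOG2_20 - 19 / (40 * math.log(2)))

    def test_gaps_excluded_from_n(self):
        prof = column_information("WW--WW..W", correct_small_sample=True)
        assert prof.n == 5

    def test_heights_sum_to_information(self):
        prof = column_information("WWPPEEEAAC", correct_small_sample=False)
        assert sum(prof.letter_heights.values()) == pytest.approx(prof.information)

    def test_all_gap_column_flagged(self):
        with pytest.raises(ValueError, match="all-gap"):
            column_information("---")
        table = alignment_logo(["W-", "W-"])
        assert math.isnan(table.loc[1, "R_bits"])

    def test_ambiguous_residue_handling(self):
        with pytest.raises(ValueError, match="X"):
            column_information("WXW")
        assert column_information("WXW", ambiguous_as_gap=True).n == 2

    def test_monotone_decrease_toward_uniform(self):
        """R decreases along point-mass -> uniform mixtures (majorization)."""
        rng = np.random.default_rng(0)
        n = 4000
        values = []
        for alpha in np.linspace(0.0, 1.0, 6):
            p = (1 - alpha) * np.eye(20)[0] + alpha * np.full(20, 1 / 20)
            column = rng.choice(list(AMINO_ACIDS), size=n, p=p)
            # use the exact mixture frequencies, not the sample, for strictness
            freqs = p[p > 0]
            entropy = -np.sum(freqs * np.log2(freqs))
            values.append(LOG2_20 - entropy)
            sampled = column_information(column, correct_small_sample=False)
            assert abs(sampled.information - values[-1]) < 0.15
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_logo_peaks_at_invariant_columns(self):
        """Synthetic conserved-region alignment: tallest stacks at the
        invariant Trp/Pro columns."""
        profiles = conserved_region_profiles(n_columns=20, seed=3)
        recs = generate_alignment(AlignmentSpec(200, profiles, seed=3))
        table = alignment_logo([str(r.seq) for r in recs])
        top2 = set(table.nlargest(2, "R_bits")["position"] - 1)
        assert top2 == {4, 12}
        assert table.loc[4, "W"] == table.loc[4, "R_bits"]


class TestComposition:
    def test_single_class(self):
        prof = composition_by_class(["PPPP"])
        assert prof.class_fractions == {"special": 1.0}

    def test_acidic_basic_split(self):
        prof = composition_by_class(["DEKR"])
        assert prof.class_fractions["acidic"] == 0.5
        assert prof.class_fractions["basic"] == 0.5

    def test_fractions_sum_to_one(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=500))
        prof = composition_by_class([seq])
        assert sum(prof.class_fractions.values()) == pytest.approx(1.0)

    def test_multinomial_recovery(self, rng):
        """10,000 residues from known class frequencies: within 3 SE each."""
        class_freqs = {"acidic": 0.3, "basic": 0.2, "special": 0.5}
        residues = {"acidic": "DE", "basic": "KR", "special": "GP"}
        draws = rng.choice(list(class_freqs), size=10_000,
                           p=list(class_freqs.values()))
        seq = "".join(rng.choice(list(residues[c])) for c in draws)
        prof = composition_by_class([seq])
        for cls, f in class_freqs.items():
            se = math.sqrt(f * (1 - f) / 10_000)
            assert abs(prof.class_fractions[cls] - f) <= 3 * se

    def test_permutation_invariance(self, rng):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        shuffled = "".join(rng.permutation(list(seq)))
        assert (
            composition_by_class([seq]).class_fractions
            == composition_by_class([shuffled]).class_fractions
        )

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="position 3"):
            composition_by_class(["AC1D"])

    def test_class_map_is_total(self):
        assert set(DEFAULT_CLASS_MAP) == set(AMINO_ACIDS)


def random_hits(rng, n=8):
    hits = []
    for i in range(n):
        start = int(rng.integers(1, 150))
        end = start + int(rng.integers(0, 60))
        hits.append(
            DomainHit("prot", f"dom{rng.integers(0, 5)}", start, end,
                      float(rng.integers(10, 100)))
        )
    return hits


def greedy_oracle(hits):
    """Independent replay of the greedy rule with plain lists."""
    remaining = list(hits)
    accepted = []
    while remaining:
        best = min(remaining, key=lambda h: (-h.score, h.start, h.domain))
        accepted.append(best)
        remaining = [
            h for h in remaining
            if h is not best and (h.end < best.start or h.start > best.end)
        ]
    return sorted(accepted, key=lambda h: h.start)


class TestArchitecture:
    def test_non_overlapping_hits_all_kept(self):
        hits = [DomainHit("p", "B", 50, 90, 10.0), DomainHit("p", "A", 1, 40, 5.0)]
        assert resolve_architecture(hits) == sorted(hits, key=lambda h: h.start)

    def test_higher_score_wins_overlap(self):
        a = DomainHit("p", "A", 1, 100, 50.0)
        b = DomainHit("p", "B", 50, 150, 60.0)
        assert resolve_architecture([a, b]) == [b]

    def test_tie_breaks_deterministic(self):
        a = DomainHit("p", "B", 10, 50, 40.0)
        b = DomainHit("p", "A", 10, 50, 40.0)
        assert resolve_architecture([a, b]) == [b]  # lexicographic name

    def test_matches_independent_greedy_oracle(self, rng):
        for _ in range(200):
            hits = random_hits(rng, n=int(rng.integers(1, 10)))
            assert resolve_architecture(hits) == greedy_oracle(hits)

    def test_disjoint_sorted_idempotent(self, rng):
        for _ in range(100):
            out = resolve_architecture(random_hits(rng))
            for h1, h2 in zip(out, out[1:]):
                assert h1.end < h2.start  # disjoint and sorted
            assert resolve_architecture(out) == out  # idempotent

    def test_multi_protein_input_rejected(self):
        with pytest.raises(ValueError, match="multiple proteins"):
            resolve_architecture(
                [DomainHit("p1", "A", 1, 5, 1.0), DomainHit("p2", "A", 1, 5, 1.0)]
            )

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError, match="start"):
            DomainHit("p", "A", 10, 5, 1.0)


class TestCooccurrence:
    def test_uniform_table(self):
        import pandas as pd

        data = pd.DataFrame(True, index=[f"g{i}" for i in range(5)],
                            columns=["A", "B"])
        table = CooccurrenceTable(data)
        assert tabulate_cooccurrence(table) == [("11", 5)]
        assert query_cooccurrence(table, ["A", "B"], "A") == (5, 5)

    def test_planted_counts_recovered(self):
        counts = {"110": 7, "101": 3, "000": 2}
        table = generate_presence_absence(
            PatternSpec(markers=("A", "B", "C"), pattern_counts=counts, seed=1)
        )
        assert dict(tabulate_cooccurrence(table)) == counts

    def test_ordering_count_desc_then_pattern_desc(self):
        counts = {"10": 3, "01": 3, "11": 5}
        table = generate_presence_absence(
            PatternSpec(markers=("A", "B"), pattern_counts=counts, seed=2)
        )
        assert tabulate_cooccurrence(table) == [("11", 5), ("10", 3), ("01", 3)]

    def test_count_conservation_on_random_tables(self, rng):
        """Sum of pattern counts equals genome count on 200 random tables."""
        import pandas as pd

        for _ in range(200):
            n_genomes = int(rng.integers(1, 40))
            n_markers = int(rng.integers(1, 6))
            data = pd.DataFrame(
                rng.integers(0, 2, size=(n_genomes, n_markers)).astype(bool),
                index=[f"g{i}" for i in range(n_genomes)],
                columns=[f"m{j}" for j in range(n_markers)],
            )
            table = CooccurrenceTable(data)
            assert sum(c for _, c in tabulate_cooccurrence(table)) == n_genomes

    def test_marker_cooccurrence_query_structure(self):
        """Default planted table mirrors the 60-genome MglA∧MglB set of which
        26 carry an intact RomR, 10 of those a Frz system."""
        table = generate_presence_absence(PatternSpec(seed=0))
        n_mglab, n_romr = query_cooccurrence(table, ["MglA", "MglB"], "RomR-C")
        assert (n_mglab, n_romr) == (60, 26)
        _, n_frz = query_cooccurrence(
            table, ["MglA", "MglB", "RomR-REC", "RomR-C"], "Frz"
        )
        assert n_frz == 10
        n_romr_total, _ = query_cooccurrence(table, ["RomR-REC"])
        assert n_romr_total == 31

    def test_empty_require_counts_all(self):
        table = generate_presence_absence(PatternSpec(seed=0))
        assert query_cooccurrence(table, [])[0] == table.n_genomes

    def test_unknown_marker_rejected(self):
        table = generate_presence_absence(PatternSpec(seed=0))
        with pytest.raises(ValueError, match="nope"):
            query_cooccurrence(table, ["nope"])

    def test_duplicate_genome_ids_rejected(self):
        import pandas as pd

        data = pd.DataFrame(True, index=["g", "g"], columns=["A"])
        with pytest.raises(ValueError, match="unique"):
            CooccurrenceTable(data)
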