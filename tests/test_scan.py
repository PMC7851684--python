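"""Binding-site search rules, classification, amplicons, and reporting."""

import numpy as np
import pytest

from crossprime.scan import (
    BindingSite,
    ScanRules,
    annotate_sites,
    classify_identity,
    classify_tm,
    predict_amplicons,
    scan_primer,
    site_tm,
    summarize_hits,
)
from crossprime.seqio import Feature, GenomeRecord
from crossprime.synth import PlantedSiteSpec, plant_sites, random_background
from crossprime.thermo import (
    DEFAULT_PARAMS,
    DegeneratePrimer,
    expand_degenerate,
    melting_temperature,
    reverse_complement,
)


def brute_force_scan(primer_seq, genome_seq, rules=None, params=None):
    """Independent oracle: test every window x strand x expansion against
    the rules, then keep the best expansion per (position, strand)."""
    rules = rules or ScanRules()
    params = params or DEFAULT_PARAMS
    L, G = len(primer_seq), len(genome_seq)
    best = {}
    for expansion in expand_degenerate(primer_seq):
        tm_perfect = melting_temperature(expansion, params)
        for strand in ("+", "-"):
            template = genome_seq if strand == "+" else reverse_complement(genome_seq)
            for p in range(G - L + 1):
                window = template[p : p + L]
                mask = [a == b for a, b in zip(expansion, window)]
                matches = sum(mask)
                mism = L - matches
                if matches < rules.min_matched or mism > rules.max_mismatches:
                    continue
                if rules.exclude_5prime_mismatch and not mask[0]:
                    continue
                if rules.require_3prime_match and not mask[-1]:
                    continue
                if rules.forbid_consecutive_mismatches and any(
                    not a and not b for a, b in zip(mask, mask[1:])
                ):
                    continue
                tm = tm_perfect - params.mismatch_penalty * mism
                if not (rules.tm_window[0] <= tm <= rules.tm_window[1]):
                    continue
                start = p if strand == "+" else G - p - L
                key = (start, strand)
                cand = (matches, expansion)
                prev = best.get(key)
                if prev is None or cand[0] > prev[0] or (cand[0] == prev[0] and cand[1] < prev[1]):
                    best[key] = cand
    return {(s, st, m, e) for (s, st), (m, e) in best.items()}


class TestScanPrimer:
    def test_exact_substring_hit(self):
        genome = "T" * 50 + "ACGTACGTACGTACGTAC" + "G" * 50
        sites = scan_primer("ACGTACGTACGTACGTAC", genome)
        exact = [s for s in sites if s.start == 50 and s.strand == "+"]
        assert exact and exact[0].matches == 18
        assert exact[0].mismatches == 0
        assert exact[0].identity == 100.0
        assert exact[0].end == 68

    def test_planted_two_mismatches_scores_90_5(self, background):
        primer = "CTGGCTGCCCTGACTAATAAC"  # 21-mer
        genome, truth = plant_sites(
            background, primer, [PlantedSiteSpec(mismatches=2)], seed=8
        )
        sites = scan_primer(primer, genome)
        t = truth[0]
        hit = [s for s in sites if s.start == t.start and s.strand == t.strand]
        assert hit
        assert hit[0].matches == 19
        assert hit[0].identity == pytest.approx(19 * 100 / 21)
        assert round(hit[0].identity, 1) == 90.5
        assert hit[0].mismatch_positions == t.mismatch_positions

    def test_genome_shorter_than_primer(self):
        assert scan_primer("ACGTACGTACGTACGTAC", "ACGT") == []

    def test_degeneracy_cap_is_error(self):
        with pytest.raises(ValueError, match="cap"):
            scan_primer("N" * 18, "ACGT" * 100, ScanRules(max_degeneracy=16))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_oracle_on_random_templates(self, seed):
        rng = np.random.default_rng(seed)
        genome = random_background(2000, 50, rng)
        primer = "AGAASAYCCAGCGCCACGAM"  # degeneracy 8
        # plant a few compliant sites so the comparison is not vacuous
        genome, _ = plant_sites(
            genome,
            primer,
            [PlantedSiteSpec(mismatches=m, strand=st) for m in (0, 1, 2) for st in "+-"],
            seed=seed + 100,
        )
        got = {
            (s.start, s.strand, s.matches, s.expansion_used)
            for s in scan_primer(primer, genome)
        }
        assert got == brute_force_scan(primer, genome)

    def test_mismatch_budget_depends_on_length(self):
        # joint constraints: matches >= 18 and mismatches <= 3 mean an
        # 18-mer admits 0 mismatches, a 20-mer 2, a 21..23-mer 3
        rng = np.random.default_rng(77)
        for L, budget in ((18, 0), (19, 1), (20, 2), (21, 3), (22, 3), (23, 3)):
            primer = random_background(L, 50, rng)
            bg = random_background(400, 50, np.random.default_rng(1000 + L))
            ok_spec = [PlantedSiteSpec(mismatches=budget)]
            genome, truth = plant_sites(bg, primer, ok_spec, seed=L)
            sites = scan_primer(primer, genome)
            assert any(s.start == truth[0].start for s in sites), f"L={L}"
            with pytest.raises(ValueError, match="violates the scan rules"):
                plant_sites(bg, primer, [PlantedSiteSpec(mismatches=budget + 1)], seed=L)

    def test_reverse_strand_symmetry(self, background):
        primer = "TGGYGGCGCWGTACGAAAGC"
        genome, _ = plant_sites(
            background,
            primer,
            [PlantedSiteSpec(mismatches=1, strand="+"), PlantedSiteSpec(mismatches=1, strand="-")],
            seed=5,
        )
        fwd = scan_primer(primer, genome)
        mirrored = scan_primer(reverse_complement(primer), reverse_complement(genome))
        G = len(genome)
        got = {(s.start, s.strand) for s in fwd}
        # reverse-complementing both primer and template mirrors the
        # coordinate but preserves which strand is bound
        mirrored_back = {(G - s.end, s.strand) for s in mirrored}
        assert got == mirrored_back

    def test_all_reported_sites_satisfy_invariants(self, background):
        primer = DegeneratePrimer(name="p", sequence="CAYACCTGYACYCATGGGGC")
        genome, _ = plant_sites(
            background, primer, [PlantedSiteSpec(mismatches=m) for m in (0, 1, 2)], seed=3
        )
        for s in scan_primer(primer, genome):
            L = len(primer.sequence)
            assert s.matches + s.mismatches == L
            assert s.matches >= 18 and s.mismatches <= 3
            assert s.identity > 80.0
            assert all(b - a >= 2 for a, b in zip(s.mismatch_positions, s.mismatch_positions[1:]))
            assert 1 not in s.mismatch_positions and L not in s.mismatch_positions

    def test_template_n_never_matches(self):
        primer = "ACGTACGTACGTACGTAC"
        genome = "T" * 30 + "ACGTACGTACGTACGTAC".replace("T", "N", 1) + "G" * 30
        # N at one internal position: an 18-mer admits zero mismatches
        assert all(s.start != 30 for s in scan_primer(primer, genome))


class TestClassification:
    @pytest.mark.parametrize(
        "identity,bin_label",
        [
            (100.0, "100%"),
            (90.5, "90.0-99.9%"),
            (20 * 100 / 23, "80.0-89.9%"),  # 86.96
            (99.95, "100%"),  # rounds to 100.0
        ],
    )
    def test_identity_bins(self, identity, bin_label):
        assert classify_identity(identity) == bin_label

    def test_identity_at_or_below_80_is_error(self):
        with pytest.raises(ValueError):
            classify_identity(80.0)

    @pytest.mark.parametrize(
        "tm,bin_label",
        [
            (49.9, "<=49.9"),
            (50.0, "50.0-54.9"),
            (55.0, "55.0-59.9"),
            (64.99, "60.0-64.9"),
            (65.0, "65.0-69.9"),
            (70.0, ">=70.0"),
            (30.0, "<=49.9"),
        ],
    )
    def test_tm_bins(self, tm, bin_label):
        assert classify_tm(tm) == bin_label


def _mk_site(expansion, start, strand, mism=0, genome_id="g"):
    L = len(expansion)
    return BindingSite(
        primer_name="p",
        expansion_used=expansion,
        genome_id=genome_id,
        start=start,
        end=start + L,
        strand=strand,
        matches=L - mism,
        mismatches=mism,
        identity=(L - mism) * 100 / L,
        duplex_tm=0.0,
        mismatch_positions=(),
    )


class TestSiteTm:
    def test_zero_mismatches_equals_expansion_tm(self):
        s = _mk_site("CCTGTTTACATTGGGGTCGTT", 0, "+")
        assert site_tm(s) == pytest.approx(melting_temperature(s.expansion_used))

    def test_penalty_per_mismatch(self):
        s = _mk_site("CCTGTTTACATTGGGGTCGTT", 0, "+", mism=2)
        expected = melting_temperature(s.expansion_used) - 10.0
        assert site_tm(s) == pytest.approx(expected)

    def test_never_exceeds_perfect_duplex(self, background):
        primer = "CTGGCTGCCCTGACTAATAAC"
        genome, _ = plant_sites(
            background, primer, [PlantedSiteSpec(mismatches=m) for m in (0, 1, 2, 3)], seed=2
        )
        perfect = melting_temperature(primer)
        for s in scan_primer(primer, genome):
            assert site_tm(s) <= perfect + 1e-9


class TestAmplicons:
    def test_product_size_arithmetic(self):
        fwd = _mk_site("A" * 20, 100, "+")
        rev = _mk_site("A" * 20, 300, "-")  # 5' end at template position 319
        amps = predict_amplicons([fwd], [rev])
        assert len(amps) == 1
        assert amps[0].product_size == 220
        assert amps[0].intended  # within the default 180-240 window

    def test_same_location_same_orientation_never_amplifies(self):
        a = _mk_site("A" * 20, 500, "-")
        b = _mk_site("A" * 20, 500, "-")
        assert predict_amplicons([a], [b]) == []

    def test_divergent_orientation_never_amplifies(self):
        fwd = _mk_site("A" * 20, 300, "+")
        rev = _mk_site("A" * 20, 100, "-")  # upstream of the forward site
        assert predict_amplicons([fwd], [rev]) == []

    def test_planted_pairs_match_brute_force_pairing(self):
        # 3 convergent pairs and 2 same-strand decoy pairs
        fwd_sites = [
            _mk_site("A" * 20, 100, "+"),
            _mk_site("A" * 20, 1000, "+"),
            _mk_site("A" * 20, 2000, "+"),
            _mk_site("A" * 20, 3000, "-"),  # decoy: same strand as its partner
        ]
        rev_sites = [
            _mk_site("A" * 20, 290, "-"),
            _mk_site("A" * 20, 1195, "-"),
            _mk_site("A" * 20, 2210, "-"),
            _mk_site("A" * 20, 3100, "-"),  # pairs only with + forwards far away
        ]
        rules = ScanRules(max_product_size=500)
        got = {
            (a.forward_site.start, a.reverse_site.start, a.product_size)
            for a in predict_amplicons(fwd_sites, rev_sites, rules)
        }
        expected = set()
        for f in fwd_sites:
            for r in rev_sites:
                if f.strand == r.strand:
                    continue
                p, m = (f, r) if f.strand == "+" else (r, f)
                if p.start <= m.start and p.end <= m.end and m.end - p.start <= 500:
                    expected.add((f.start, r.start, m.end - p.start))
        assert got == expected
        assert len(got) == 3

    def test_max_product_size_respected(self):
        fwd = _mk_site("A" * 20, 0, "+")
        rev = _mk_site("A" * 20, 9000, "-")
        assert predict_amplicons([fwd], [rev]) == []

    def test_intended_requires_target_overlap_when_features_given(self):
        fwd = _mk_site("A" * 20, 100, "+")
        rev = _mk_site("A" * 20, 300, "-")
        target = Feature("tgt", "efflux pump", "CDS", 90, 400, "+", "g")
        elsewhere = Feature("other", "efflux pump", "CDS", 5000, 6000, "+", "g")
        assert predict_amplicons([fwd], [rev], intended_features=[target])[0].intended
        amp = predict_amplicons([fwd], [rev], intended_features=[elsewhere])[0]
        assert not amp.intended


class TestAnnotation:
    FEATURES = [
        Feature("g1", "RND efflux transporter", "CDS", 100, 400, "+", "g"),
        Feature("g2", "conserved protein of unknown function", "CDS", 600, 900, "-", "g"),
    ]

    def test_site_inside_feature(self):
        s = annotate_sites([_mk_site("A" * 20, 150, "+")], self.FEATURES)[0]
        assert s.target_locus == "g1"
        assert s.target_product == "RND efflux transporter"

    def test_intergenic_site_is_noncoding(self):
        s = annotate_sites([_mk_site("A" * 20, 450, "+")], self.FEATURES)[0]
        assert s.target_locus == "noncoding region"

    def test_straddling_site_assigned_by_midpoint(self):
        # site [95, 115): midpoint 104 falls inside g1 [100, 400)
        inside = annotate_sites([_mk_site("A" * 20, 95, "+")], self.FEATURES)[0]
        assert inside.target_locus == "g1"
        # site [85, 105): midpoint 94 falls before g1
        outside = annotate_sites([_mk_site("A" * 20, 85, "+")], self.FEATURES)[0]
        assert outside.target_locus == "noncoding region"

    def test_hypothetical_umbrella_collapsed(self):
        s = annotate_sites([_mk_site("A" * 20, 700, "+")], self.FEATURES)[0]
        assert s.target_product == "hypothetical protein"


class TestSummarizeHits:
    def test_planted_identity_spectrum_counts(self):
        rng = np.random.default_rng(55)
        primer = DegeneratePrimer(name="probe", sequence="CTGGCTGCCCTGACTAATAAC")
        bg = random_background(5000, 50, rng)
        genome, _ = plant_sites(
            bg, primer,
            [PlantedSiteSpec(mismatches=0),  # 100%
             PlantedSiteSpec(mismatches=1),  # 95.2 -> 90.0-99.9%
             PlantedSiteSpec(mismatches=3)],  # 85.7 -> 80.0-89.9%
            seed=6,
        )
        counts, edges = summarize_hits(
            [primer], [GenomeRecord(id="g", description="", sequence=genome)]
        )
        assert counts.loc["probe", "100%"] == 1
        assert counts.loc["probe", "90.0-99.9%"] == 1
        assert counts.loc["probe", "80.0-89.9%"] == 1
        assert len(edges) == int(counts.loc["probe"].sum())
        assert (edges["position"] >= 1).all()  # reported 1-based

    def test_edge_list_conserves_site_count(self, community):
        import crossprime as cp

        _, paths = community
        genomes = cp.read_fasta(paths["fasta"])
        primers = cp.panel_primers(cp.read_primer_table(paths["primers"]))
        counts, edges = summarize_hits(primers, genomes)
        total = sum(
            len(scan_primer(p, g)) for p in primers for g in genomes
        )
        assert len(edges) == total == int(counts.to_numpy().sum())
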