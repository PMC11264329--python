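"""Cassette windows, oligo emission, and in-silico Golden Gate assembly."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gvscreen import (
    AssemblyError,
    ECOLI_TABLE,
    MutationSpec,
    TilingError,
    build_acceptor,
    design_site_saturation,
    emit_oligos,
    make_member,
    random_parent_cds,
    simulate_assembly,
    tile_cds,
)
from gvscreen.cassette import BSAI, OligoDesignError, digest, is_palindromic
from gvscreen.codons import reverse_complement

from conftest import parent_with_protein


class TestTiling:
    def test_windows_tile_without_gap_or_overlap(self, gvpa_like):
        windows = tile_cds(gvpa_like, max_variable_len=90)
        assert len(windows) == 3
        covered = []
        for w in windows:
            covered.extend(range(w.start, w.end + 1))
        # exhaustive scan: every codon index exactly once
        assert covered == list(range(1, gvpa_like.n_codons + 1))
        assert all(w.n_codons * 3 <= 90 for w in windows)

    def test_short_cds_single_window(self):
        parent = random_parent_cds(10, seed=1)
        windows = tile_cds(parent, max_variable_len=90)
        assert len(windows) == 1
        assert (windows[0].start, windows[0].end) == (1, 10)

    def test_mid_codon_boundary_rejected(self, gvpa_like):
        with pytest.raises(TilingError):
            tile_cds(gvpa_like, boundaries=[23.5])

    def test_explicit_boundaries_respected(self, gvpa_like):
        windows = tile_cds(gvpa_like, max_variable_len=200, boundaries=[36])
        assert [(w.start, w.end) for w in windows] == [(1, 35), (36, 70)]

    def test_overhangs_distinct_and_non_palindromic(self, gvpb_like):
        windows = tile_cds(gvpb_like, max_variable_len=90)
        overhangs = [oh for w in windows for oh in (w.overhang_5, w.overhang_3)]
        assert len(set(overhangs)) == len(overhangs)
        for oh in overhangs:
            assert not is_palindromic(oh)
            assert reverse_complement(oh) not in set(overhangs) - {oh}


class TestOligos:
    def test_same_window_members_share_flanks(self, gvpa_like):
        windows = tile_cds(gvpa_like)
        members = design_site_saturation(gvpa_like, codon_range=(3, 4))
        oligos = emit_oligos(members, windows, gvpa_like)
        prefixes = {o.full_oligo.split(o.variable_region)[0] for o in oligos}
        suffixes = {o.full_oligo.split(o.variable_region)[1] for o in oligos}
        assert len(prefixes) == 1 and len(suffixes) == 1
        assert len({o.variable_region for o in oligos}) == len(oligos)

    def test_wild_type_variable_region_equals_parent_window(self, gvpa_like):
        windows = tile_cds(gvpa_like)
        wt = make_member(gvpa_like, [])
        (oligo,) = emit_oligos([wt], windows, gvpa_like)
        w = oligo.window
        assert oligo.variable_region == gvpa_like.sequence[w.variable_slice()]
        assert oligo.recodings == ()

    def test_exactly_two_inward_sites(self, gvpa_like):
        windows = tile_cds(gvpa_like)
        members = design_site_saturation(gvpa_like, codon_range=(10, 10))
        for oligo in emit_oligos(members, windows, gvpa_like):
            frags = digest(oligo.full_oligo)
            assert len(frags) == 3  # two cuts release the cassette
            assert BSAI.recognition not in oligo.variable_region
            assert BSAI.recognition_rc not in oligo.variable_region

    def test_mutation_creating_site_is_recoded_and_reported(self):
        # parent has GAG at codon 3; mutating codon 4 to T (preferred ACC)
        # would write GAGACC into the variable region
        parent = parent_with_protein("MAEKLVDNQW", id="site-maker")
        assert parent.sequence[6:9] == "GAA"
        parent = dataclasses.replace(parent, sequence=parent.sequence[:6] + "GAG" + parent.sequence[9:])
        windows = tile_cds(parent)
        member = make_member(parent, [MutationSpec(4, "K", "T")])
        assert "GAGACC" in member.cds  # the raw mutant would carry a site
        (oligo,) = emit_oligos([member], windows, parent)
        assert "GAGACC" not in oligo.variable_region
        assert "GGTCTC" not in oligo.variable_region
        assert len(oligo.recodings) == 1
        # protein is preserved despite the synonymous rewrite
        w = oligo.window
        assembled_protein = ECOLI_TABLE.translate(oligo.variable_region)
        expected = ECOLI_TABLE.translate(member.cds[w.variable_slice()])
        assert assembled_protein == expected

    def test_mutations_spanning_two_windows_error(self, gvpa_like):
        windows = tile_cds(gvpa_like, max_variable_len=90)
        spanning = make_member(
            gvpa_like,
            [
                MutationSpec(2, gvpa_like.protein[1], "W"),
                MutationSpec(69, gvpa_like.protein[68], "W"),
            ],
        )
        with pytest.raises(OligoDesignError, match="single cassette window"):
            emit_oligos([spanning], windows, gvpa_like)


class TestAssembly:
    def test_wild_type_round_trip_is_identity(self, gvpa_like):
        windows = tile_cds(gvpa_like)
        wt = make_member(gvpa_like, [])
        (oligo,) = emit_oligos([wt], windows, gvpa_like)
        acceptor = build_acceptor(gvpa_like, oligo.window)
        assert simulate_assembly(oligo, acceptor) == gvpa_like.sequence

    def test_t6a_cassette_assembles_to_t6a_protein(self, gvpa_like):
        windows = tile_cds(gvpa_like)
        member = make_member(gvpa_like, [MutationSpec(6, "T", "A")])
        (oligo,) = emit_oligos([member], windows, gvpa_like)
        acceptor = build_acceptor(gvpa_like, oligo.window)
        cds = simulate_assembly(oligo, acceptor)
        protein = ECOLI_TABLE.translate(cds)
        assert protein[5] == "A"
        assert protein[:5] + protein[6:] == gvpa_like.protein[:5] + gvpa_like.protein[6:]

    def test_scrambled_overhangs_fail_assembly(self, gvpa_like):
        windows = tile_cds(gvpa_like)
        wt = make_member(gvpa_like, [])
        (oligo,) = emit_oligos([wt], windows, gvpa_like)
        acceptor = build_acceptor(gvpa_like, oligo.window)
        w = oligo.window
        scrambled = dataclasses.replace(
            oligo,
            full_oligo=oligo.full_oligo.replace(
                BSAI.recognition + "A" + w.overhang_5,
                BSAI.recognition + "A" + reverse_complement(w.overhang_5),
                1,
            ),
        )
        with pytest.raises(AssemblyError):
            simulate_assembly(scrambled, acceptor)

    def test_mismatched_window_acceptor_fails(self, gvpa_like):
        windows = tile_cds(gvpa_like, max_variable_len=90)
        assert len(windows) >= 2
        members = design_site_saturation(gvpa_like, codon_range=(2, 2))
        oligos = emit_oligos(members[:1], windows, gvpa_like)
        wrong_acceptor = build_acceptor(gvpa_like, windows[-1])
        with pytest.raises(AssemblyError):
            simulate_assembly(oligos[0], wrong_acceptor)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_fuzzed_members_assemble_to_intended_protein(self, seed):
        """Random parents, random mutation sets: emitted oligos always
        assemble to a CDS translating to the intended mutant protein."""
        import numpy as np

        rng = np.random.default_rng(seed)
        parent = random_parent_cds(int(rng.integers(15, 45)), seed=seed)
        try:
            windows = tile_cds(parent, max_variable_len=60)
        except TilingError:
            return  # rare sequence-dependent overhang clash; reported, not silent
        window = windows[int(rng.integers(0, len(windows)))]
        k = int(rng.integers(1, min(3, window.n_codons) + 1))
        positions = rng.choice(
            np.arange(window.start, window.end + 1), size=k, replace=False
        )
        specs = []
        for pos in sorted(int(p) for p in positions):
            parent_aa = parent.protein[pos - 1]
            choices = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != parent_aa]
            specs.append(MutationSpec(pos, parent_aa, choices[int(rng.integers(0, 19))]))
        member = make_member(parent, specs)
        (oligo,) = emit_oligos([member], windows, parent)
        acceptor = build_acceptor(parent, oligo.window)
        cds = simulate_assembly(oligo, acceptor)
        assert ECOLI_TABLE.translate(cds) == ECOLI_TABLE.translate(member.cds)
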