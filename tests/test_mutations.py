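"""CIGAR-walk annotation, variant collation, source rules, spectra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grnavar import (
    AnnotationError,
    ConsensusMolecule,
    MutationEvent,
    annotate_all,
    annotate_mutations,
    classify_source,
    collate_variants,
    events_to_string,
    mutation_spectrum,
    per_cell_mutation_frequency,
)
from grnavar.mutations import AnnotatedMolecule
from grnavar.simulate import apply_events


def _mol(reference, guide="gA", seq=None, cigar=None, pos=0, cb="c1", umi="u1"):
    ref_seq = reference.contigs[guide]
    seq = ref_seq if seq is None else seq
    cigar = cigar if cigar is not None else ((0, len(seq)),)
    return ConsensusMolecule(
        cell_barcode=cb,
        umi=umi,
        guide_id=guide,
        sequence=seq,
        full_sequence=seq,
        contig=guide,
        pos=pos,
        cigar=cigar,
        n_reads=2,
        n_support=2,
    )


class TestAnnotateMutations:
    def test_perfect_match_is_intact(self, small_reference):
        assert annotate_mutations(_mol(small_reference), small_reference) == ()

    def test_partial_span_perfect_match_is_intact(self, small_reference):
        ref = small_reference.contigs["gA"]
        mol = _mol(small_reference, seq=ref[5:45], cigar=((0, 40),), pos=5)
        assert annotate_mutations(mol, small_reference) == ()

    def test_single_substitution_in_spacer(self, small_reference):
        ann = small_reference.annotations["gA"]
        ref = small_reference.contigs["gA"]
        pos = ann.spacer.start + 5
        alt = "T" if ref[pos] != "T" else "A"
        seq = ref[:pos] + alt + ref[pos + 1 :]
        events = annotate_mutations(_mol(small_reference, seq=seq), small_reference)
        assert len(events) == 1
        ev = events[0]
        assert (ev.kind, ev.position, ev.ref_allele, ev.alt_allele) == (
            "substitution",
            pos,
            ref[pos],
            alt,
        )
        assert ev.region == "spacer"

    def test_single_t_deletion_in_scaffold_tetramer(self, small_reference):
        # scaffold begins GTTTT; deleting one T leaves a deletion event
        ann = small_reference.annotations["gA"]
        ref = small_reference.contigs["gA"]
        scaffold = next(r for r in ann.regions if r.label == "scaffold")
        tpos = ref.index("TTTT", scaffold.start)
        seq = ref[:tpos] + ref[tpos + 1 :]
        cigar = ((0, tpos), (2, 1), (0, len(ref) - tpos - 1))
        events = annotate_mutations(
            _mol(small_reference, seq=seq, cigar=cigar), small_reference
        )
        assert [e.kind for e in events] == ["deletion"]
        assert events[0].region == "scaffold"
        assert events[0].ref_allele == "T"

    def test_insertion_anchored_to_following_base(self, small_reference):
        ref = small_reference.contigs["gA"]
        seq = ref[:10] + "GG" + ref[10:]
        cigar = ((0, 10), (1, 2), (0, len(ref) - 10))
        events = annotate_mutations(
            _mol(small_reference, seq=seq, cigar=cigar), small_reference
        )
        assert [(e.kind, e.position, e.alt_allele) for e in events] == [
            ("insertion", 10, "GG")
        ]

    def test_softclip_is_evidence_of_deviation(self, small_reference):
        ref = small_reference.contigs["gA"]
        seq = "CCCC" + ref[:40]
        cigar = ((4, 4), (0, 40))
        events = annotate_mutations(
            _mol(small_reference, seq=seq, cigar=cigar), small_reference
        )
        assert [e.kind for e in events] == ["softclip"]
        assert events[0].position == 0

    def test_cigar_sequence_mismatch_excluded_with_record(self, small_reference):
        bad = _mol(small_reference, seq="ACGT", cigar=((0, 10),))
        with pytest.raises(AnnotationError):
            annotate_mutations(bad, small_reference)
        errors: list[str] = []
        out = annotate_all([bad, _mol(small_reference)], small_reference, errors=errors)
        assert len(out) == 1 and len(errors) == 1

    def test_one_substitution_is_never_intact(self, small_reference):
        """Strictness: even a single mismatch (1-Hamming) is a mutant call."""
        ref = small_reference.contigs["gA"]
        for pos in range(0, len(ref), 7):
            alt = "A" if ref[pos] != "A" else "C"
            seq = ref[:pos] + alt + ref[pos + 1 :]
            events = annotate_mutations(_mol(small_reference, seq=seq), small_reference)
            assert events != ()

    def test_intact_iff_hamming_zero_and_equal_length(self, small_reference):
        """Oracle: over full-span all-M alignments, intactness is exactly
        Hamming distance 0 at equal length."""
        ref = small_reference.contigs["gA"]
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = list(ref)
            n_mut = int(rng.integers(0, 3))
            for p in rng.choice(len(s), size=n_mut, replace=False):
                s[p] = "ACGT"[int(rng.integers(4))]
            seq = "".join(s)
            hamming = sum(a != b for a, b in zip(seq, ref))
            events = annotate_mutations(_mol(small_reference, seq=seq), small_reference)
            assert (events == ()) == (hamming == 0)


@settings(max_examples=100, deadline=None)
@given(data=st.data())
def test_reconstruction_identity(small_reference, data):
    """Applying the annotated events back onto the reference reproduces the
    consensus sequence (events without skips/soft clips)."""
    ref = small_reference.contigs["gA"]
    ann = small_reference.annotations["gA"]
    n_events = data.draw(st.integers(0, 3))
    positions = data.draw(
        st.lists(
            st.integers(0, len(ref) - 2), min_size=n_events, max_size=n_events, unique=True
        )
    )
    events = []
    for pos in sorted(positions):
        kind = data.draw(st.sampled_from(["substitution", "deletion", "insertion"]))
        if kind == "substitution":
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref[pos]]))
            events.append(MutationEvent(pos, kind, ref[pos], alt, ann.label_at(pos)))
        elif kind == "deletion":
            events.append(MutationEvent(pos, kind, ref[pos], "", ann.label_at(pos)))
        else:
            events.append(MutationEvent(pos, kind, "", "GA", ann.label_at(pos)))
    events = tuple(events)
    seq, cigar = apply_events(ref, events)
    recovered = annotate_mutations(
        _mol(small_reference, seq=seq, cigar=cigar), small_reference
    )
    seq_again, _ = apply_events(ref, recovered)
    assert seq_again == seq


class TestCollateVariants:
    def test_grouping_and_suffixes(self, small_reference):
        ann = small_reference.annotations["gA"]
        e1 = (MutationEvent(3, "substitution", "A", "T", ann.label_at(3)),)
        e2 = (MutationEvent(9, "substitution", "C", "T", ann.label_at(9)),)
        annotated = [
            AnnotatedMolecule(_mol(small_reference, cb=f"c{i}", umi=f"u{i}"), ev)
            for i, ev in enumerate([e1, e1, e1, e2, ()])
        ]
        variants, table = collate_variants(annotated)
        names = {v.variant_name: v for v in variants}
        assert set(names) == {"gA", "gA.1", "gA.2"}
        assert names["gA.1"].events == e1  # more UMIs -> lower suffix
        assert names["gA.1"].n_umis == 3 and names["gA.1"].n_cells == 3
        assert names["gA"].is_intact
        assert len(table) == 5

    def test_umi_conservation_per_guide(self, small_reference):
        rng = np.random.default_rng(2)
        ref = small_reference.contigs["gA"]
        ann = small_reference.annotations["gA"]
        annotated = []
        for i in range(30):
            if rng.random() < 0.4:
                pos = int(rng.integers(len(ref)))
                alt = "ACGT"[int(rng.integers(4))]
                ev = (
                    (MutationEvent(pos, "substitution", ref[pos], alt, ann.label_at(pos)),)
                    if alt != ref[pos]
                    else ()
                )
            else:
                ev = ()
            annotated.append(
                AnnotatedMolecule(_mol(small_reference, cb="c1", umi=f"u{i}"), ev)
            )
        variants, _ = collate_variants(annotated)
        assert sum(v.n_umis for v in variants) == len(annotated)

    def test_same_mutation_in_two_cells_is_one_variant(self, small_reference):
        ann = small_reference.annotations["gA"]
        ev = (MutationEvent(4, "substitution", "A", "G", ann.label_at(4)),)
        annotated = [
            AnnotatedMolecule(_mol(small_reference, cb=cb, umi=f"u{i}"), ev)
            for i, cb in enumerate(["c1", "c2"])
        ]
        variants, _ = collate_variants(annotated)
        assert len(variants) == 1 and variants[0].n_cells == 2


def _scenario_table(small_reference, spec):
    """Build annotated molecules from (cell, n_intact, n_mutant) tuples
    sharing one mutant event unless ``unique_per_cell``."""
    ann = small_reference.annotations["gA"]
    shared = (MutationEvent(6, "substitution", "G", "A", ann.label_at(6)),)
    annotated = []
    u = 0
    for cell, n_intact, n_mutant in spec:
        for _ in range(n_intact):
            annotated.append(
                AnnotatedMolecule(_mol(small_reference, cb=cell, umi=f"u{u}"), ())
            )
            u += 1
        for _ in range(n_mutant):
            annotated.append(
                AnnotatedMolecule(_mol(small_reference, cb=cell, umi=f"u{u}"), shared)
            )
            u += 1
    return collate_variants(annotated)


class TestClassifySource:
    def test_multi_cell_variant_is_virus_pool(self, small_reference):
        variants, table = _scenario_table(
            small_reference, [("c1", 0, 3), ("c2", 0, 2), ("c3", 0, 1), ("c4", 2, 0), ("c5", 1, 0)]
        )
        calls = classify_source(variants, table)
        assert set(calls.scenario) == {"virus_pool"}
        assert len(calls) == 3  # one call per (variant, cell)

    def test_sole_mutant_cell_all_umis_mutant(self, small_reference):
        variants, table = _scenario_table(small_reference, [("c1", 0, 4), ("c2", 3, 0)])
        calls = classify_source(variants, table)
        assert list(calls.scenario) == ["transduction_or_subclone"]

    def test_single_mutant_umi_next_to_intact_is_cdna_prep(self, small_reference):
        variants, table = _scenario_table(small_reference, [("c1", 56, 1), ("c2", 3, 0)])
        calls = classify_source(variants, table)
        assert list(calls.scenario) == ["cdna_prep"]
        assert calls.n_intact_umis.iloc[0] == 56

    def test_both_supported_by_multiple_umis_is_integration_duplication(
        self, small_reference
    ):
        variants, table = _scenario_table(small_reference, [("c1", 4, 3), ("c2", 3, 0)])
        calls = classify_source(variants, table)
        assert list(calls.scenario) == ["integration_duplication"]

    def test_remaining_constellation_is_ambiguous(self, small_reference):
        # >1 mutant UMI but exactly 1 intact UMI fits no scenario cleanly
        variants, table = _scenario_table(small_reference, [("c1", 1, 3), ("c2", 2, 0)])
        calls = classify_source(variants, table)
        assert list(calls.scenario) == ["ambiguous"]


class TestSpectrum:
    def test_no_variants_gives_all_zero_spectrum(self, small_reference):
        cassette = small_reference.annotations["gA"]
        spec = mutation_spectrum([], cassette)
        assert (spec["count"] == 0).all()
        assert len(spec) == cassette.end

    def test_planted_positions_recovered_with_cell_weights(self, small_reference):
        cassette = small_reference.annotations["gA"]
        variants, _ = _scenario_table(small_reference, [("c1", 0, 2), ("c2", 0, 1)])
        spec = mutation_spectrum(variants, cassette)
        assert spec.loc[spec.position == 6, "count"].item() == 2  # two cells
        assert spec["count"].sum() == 2

    def test_mask_tso_zeroes_minus2_to_0_before_spacer(self, small_reference):
        cassette = small_reference.annotations["gA"]
        s = cassette.spacer.start
        ref = small_reference.contigs["gA"]
        variants = []
        for i, pos in enumerate([s - 2, s - 1, s, s + 1]):
            ev = (MutationEvent(pos, "substitution", ref[pos], "N", cassette.label_at(pos)),)
            variants.append(
                type("V", (), {"events": ev, "n_cells": 1, "n_umis": 1})()
            )
        masked = mutation_spectrum(variants, cassette, mask_tso=True)
        unmasked = mutation_spectrum(variants, cassette, mask_tso=False)
        assert unmasked["count"].sum() == 4
        assert masked["count"].sum() == 1
        assert masked.loc[masked.position == s + 1, "count"].item() == 1

    def test_per_cell_frequency_arithmetic(self, small_reference):
        annotated = [
            AnnotatedMolecule(
                _mol(small_reference, cb="c1"),
                (MutationEvent(3, "substitution", "A", "T", "spacer"),),
            ),
            AnnotatedMolecule(_mol(small_reference, cb="c2", umi="u2"), ()),
        ]
        freq = per_cell_mutation_frequency(annotated, profiled_length=100)
        assert freq["c1"] == pytest.approx(10.0)  # 1 position / 100 nt * 1000
        assert freq["c2"] == 0.0
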