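"""Filter-cascade rules, audit-report bookkeeping, gene-set nesting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cladecal as cc
from cladecal._errors import SchemaError
from cladecal.marker_filter import ExonAlignment


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "exon", "species", "bitscore", "bitscore_threshold",
                 "dnds", "gc", "present", "length", "ref_start", "ref_end"],
    )


@pytest.fixture
def hand_fixture():
    """3 exons x 5 species engineered so the cascade removes exactly
    (2 sequences by bitscore, 1 by dN/dS, 1 exon by missing species)."""
    rows = []
    species = [f"s{i}" for i in range(5)]
    for exon, cfg in (
        ("e0", {"bitscore_drop": ["s1", "s2"]}),   # 2 bitscore removals
        ("e1", {"dnds_high": ["s0"]}),             # 1 dN/dS removal
        ("e2", {"absent": ["s0", "s1", "s2"]}),    # 2 present, 3 missing
    ):
        for sp in species:
            if sp in cfg.get("absent", []):
                continue
            bs = 70.0 if sp in cfg.get("bitscore_drop", []) else 100.0
            dn = 0.30 if sp in cfg.get("dnds_high", []) else 0.20
            rows.append(("g0", exon, sp, bs, 50.0, dn, 0.4, True, 300, 0, 300))
    return make_table(rows)


class TestSequenceFilters:
    def test_hand_traced_cascade_counts(self, hand_fixture):
        filtered, report = cc.apply_sequence_filters(
            hand_fixture, max_missing=2, n_species=5
        )
        frame = report.to_frame()
        assert list(frame["removed"]) == [2, 1, 1]
        assert list(frame["step"]) == [
            "relative_bitscore", "dnds", "missing_species"
        ]
        # conservation: after = before - removed, chained across steps
        assert (frame["after"] == frame["before"] - frame["removed"]).all()
        assert set(filtered["exon"]) == {"e0", "e1"}

    def test_all_pass_is_identity(self):
        rows = [("g0", "e0", f"s{i}", 100.0, 50.0, 0.1, 0.4, True, 300, 0, 300)
                for i in range(5)]
        table = make_table(rows)
        filtered, report = cc.apply_sequence_filters(table, n_species=5)
        assert len(filtered) == len(table)
        assert (report.to_frame()["removed"] == 0).all()

    def test_dnds_boundary_is_strict(self):
        """The rule removes ratios strictly above 0.25; exactly 0.25 stays."""
        rows = [
            ("g0", "e0", "s0", 100.0, 50.0, 0.25, 0.4, True, 300, 0, 300),
            ("g0", "e0", "s1", 100.0, 50.0, 0.2500001, 0.4, True, 300, 0, 300),
            ("g0", "e0", "s2", 100.0, 50.0, 0.10, 0.4, True, 300, 0, 300),
        ]
        filtered, report = cc.apply_sequence_filters(
            make_table(rows), max_missing=3, n_species=3
        )
        assert report.removed("dnds") == 1
        assert "s0" in set(filtered["species"])

    def test_idempotence(self, hand_fixture):
        once, _ = cc.apply_sequence_filters(hand_fixture, max_missing=2,
                                            n_species=5)
        twice, report = cc.apply_sequence_filters(once, max_missing=2,
                                                  n_species=5)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )
        assert (report.to_frame()["removed"] == 0).all()

    def test_missing_columns_raise(self):
        with pytest.raises(SchemaError):
            cc.apply_sequence_filters(pd.DataFrame({"gene": ["g0"]}))


def _aln(gene, exon, seqs, ref_start=0, ref_end=None, entropy=None):
    taxa = [f"t{i}" for i in range(len(seqs))]
    return ExonAlignment(
        gene, exon, taxa, seqs, ref_start,
        ref_end if ref_end is not None else ref_start + len(seqs[0]),
        entropy,
    )


class TestAlignmentFilters:
    def test_codon_with_excess_missing_is_masked(self):
        # codon 2 of 4 sequences has one site with 25% > 20% missing data
        seqs = ["ACGTTTACG", "ACG-TTACG", "ACGTTTACG", "ACGTTTACG"]
        a = _aln("g", "e", seqs)
        out, masks, report = cc.apply_alignment_filters([a], min_length=3,
                                                        min_exons=1)
        assert report.removed("codon_mask") == 1
        assert out[0].n_sites == 6
        assert list(masks[("g", "e")]) == [True, False, True]

    def test_entropy_masking_and_frame_check(self):
        seqs = ["ACGTTT", "ACGTTT"]
        a = _aln("g", "e", seqs, entropy=np.array([0.6, 0.1]))
        out, masks, _ = cc.apply_alignment_filters([a], min_length=3,
                                                   min_exons=1)
        assert out[0].n_sites == 3
        with pytest.raises(ValueError, match="divisible by 3"):
            _aln("g", "e", ["ACGT", "ACGT"])

    def test_distant_exons_drop_gene(self):
        """Exons 150 kb apart on the reference exceed the 100 kb span rule."""
        a = _aln("g", "e0", ["ACGTTT", "ACGTTT", "ACGTTT"], ref_start=0)
        b = _aln("g", "e1", ["ACGTTT", "ACGTTT", "ACGTTT"], ref_start=150_000)
        c = _aln("g", "e2", ["ACGTTT", "ACGTTT", "ACGTTT"], ref_start=500)
        _, _, report = cc.apply_alignment_filters(
            [a, b, c], min_length=3, min_exons=3
        )
        assert report.removed("gene_structure") == 3

    def test_hand_traced_full_cascade(self):
        """Planted violations: 2 masked codons, 1 short alignment, 1 GC
        outlier, 1 structural removal -- each step's count matches."""
        rng = np.random.default_rng(0)

        def clean(n_codons):
            return "".join(rng.choice(list("ACGT"), 3 * n_codons))

        keepers = [
            _aln("g1", f"e{i}", [clean(60)] * 6, ref_start=i * 200)
            for i in range(3)
        ]
        # 2 codons masked by entropy in one keeper
        ent = np.zeros(60)
        ent[[5, 10]] = 0.9
        masked = _aln("g1", "e3", [clean(60)] * 6, ref_start=700, entropy=ent)
        # short after masking: 49 of 50 codons masked -> 3 bp < 150
        short = _aln(
            "g2", "e0", [clean(50)] * 6,
            entropy=np.concatenate([np.zeros(1), np.full(49, 0.9)]),
        )
        # GC outlier: one sequence all GC, others all AT
        gc_bad = _aln("g3", "e0", ["GC" * 90] + ["AT" * 90] * 5)
        # structural: lone exon of its gene (min_exons=2)
        lone = _aln("g4", "e0", [clean(60)] * 6)
        out, _, report = cc.apply_alignment_filters(
            [*keepers, masked, short, gc_bad, lone],
            min_exons=2,
        )
        frame = report.to_frame().set_index("step")
        assert frame.loc["codon_mask", "removed"] == 2 + 49
        assert frame.loc["min_length", "removed"] == 1
        assert frame.loc["gc_sd", "removed"] == 1
        assert frame.loc["gene_structure", "removed"] == 1
        assert {(a.gene, a.exon) for a in out} == {
            ("g1", "e0"), ("g1", "e1"), ("g1", "e2"), ("g1", "e3")
        }
        assert (frame["after"] == frame["before"] - frame["removed"]).all()

    def test_concordance_and_manual_steps(self):
        alns = [_aln("g", f"e{i}", ["ACGTTT"] * 4, ref_start=i * 10)
                for i in range(4)]
        out, _, report = cc.apply_alignment_filters(
            alns, min_length=3, min_exons=2,
            concordant={("g", "e0"): False},
            manual_exclude=[],
        )
        assert report.removed("concordance") == 1
        assert report.removed("manual_exclusion") == 0
        assert len(out) == 3


class TestGeneSets:
    def test_threshold_arithmetic(self):
        metrics = pd.DataFrame(
            {
                "gene": ["permissive_only", "both", "neither"],
                "min_ess": [150, 250, 90],
                "rate": [1.5e-9, 1.3e-9, 1.0e-9],
                "rate_cv": [0.65, 0.5, 0.2],
            }
        )
        sets = cc.select_gene_sets(metrics)
        assert sets["permissive"] == {"permissive_only", "both"}
        assert sets["strict"] == {"both"}

    @settings(max_examples=100, deadline=None)
    @given(
        ess=st.lists(st.floats(1, 500), min_size=1, max_size=30),
        data=st.data(),
    )
    def test_strict_nested_in_permissive(self, ess, data):
        n = len(ess)
        rate = data.draw(
            st.lists(st.floats(1e-10, 3e-9), min_size=n, max_size=n)
        )
        cv = data.draw(st.lists(st.floats(0, 1.5), min_size=n, max_size=n))
        metrics = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(n)], "min_ess": ess,
             "rate": rate, "rate_cv": cv}
        )
        sets = cc.select_gene_sets(metrics)
        assert sets["strict"] <= sets["permissive"]
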