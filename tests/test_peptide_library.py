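"""Library enumeration, mass conventions, isobaric grouping, peak assignment
and pull-down enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermolead as tl
from thermolead.peptide_library import (
    LibraryError,
    LibrarySpec,
    MassPeak,
    Peptide,
    assign_peaks,
    enrichment_score,
    enumerate_library,
    isobaric_classes,
    peptide_mass,
)
from thermolead import synthetic_data as synth

from oracles import ATOMIC_MONO, formula_mass


@pytest.mark.parametrize(
    "positions, expected",
    [
        (("KGDE", "DE", "ST", "DE", "DE", "DE"), 128),
        (("KGDE", "DE", "S", "DE", "DE", "DE", "DE"), 128),
        (("KGDE", "DE", "T", "DE", "DE", "DE", "DE"), 128),
        (("A", "A"), 1),
    ],
)
def test_enumeration_count(positions, expected):
    spec = LibrarySpec(positions, cterm="amide")
    peptides = enumerate_library(spec)
    assert len(peptides) == expected
    assert len({p.sequence for p in peptides}) == expected


def test_empty_position_rejected():
    with pytest.raises(LibraryError):
        LibrarySpec(("KGDE", ""), cterm="amide")
    with pytest.raises(LibraryError):
        LibrarySpec(("KGDE", "DX"), cterm="amide")


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.sets(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=1, max_size=5),
        min_size=1,
        max_size=5,
    )
)
def test_enumeration_count_is_product_of_set_sizes(position_sets):
    spec = LibrarySpec(tuple("".join(sorted(s)) for s in position_sets))
    expected = int(np.prod([len(s) for s in position_sets]))
    assert len(enumerate_library(spec)) == expected


@pytest.mark.parametrize(
    "sequence, nominal_mh",
    [("EETEED", 750), ("KETEEE", 763), ("EETEEE", 764)],
)
def test_nominal_protonated_masses_of_identified_peptides(sequence, nominal_mh):
    p = Peptide(sequence, cterm="amide")
    assert peptide_mass(p, "mono", "protonated", nominal=True) == nominal_mh


def test_glycine_mass_matches_atomic_sum():
    # independent oracle: neutral glycine free acid is C2H5NO2
    expected = formula_mass({"C": 2, "H": 5, "N": 1, "O": 2})
    assert peptide_mass(Peptide("G"), "mono", "neutral") == pytest.approx(expected, abs=1e-5)
    assert expected == pytest.approx(75.03203, abs=1e-5)


def test_mono_below_average_mass(hexa_library):
    for p in hexa_library[:10]:
        assert p.mono_mass < p.avg_mass


def test_mass_additivity_of_free_acid_concatenation():
    water = formula_mass({"H": 2, "O": 1})
    p, q = Peptide("KES"), Peptide("EEE")
    whole = Peptide("KESEEE")
    assert whole.mono_mass == pytest.approx(p.mono_mass + q.mono_mass - water, abs=1e-6)


def test_unknown_residue_rejected():
    with pytest.raises(LibraryError):
        Peptide("KEZ")


def test_isobaric_class_of_identified_750_peak(hexa_classes):
    cls = next(c for c in hexa_classes if "EETEED-NH2" in c.labels)
    assert sorted(cls.labels) == sorted(
        ["EETEED-NH2", "EETEDE-NH2", "DETEEE-NH2", "EETDEE-NH2", "EDTEEE-NH2", "EESEEE-NH2"]
    )


def test_ser_glu_equals_thr_asp_mass_degeneracy():
    a, b = Peptide("EESEEE", "amide"), Peptide("EETEED", "amide")
    assert dict(a.composition) == dict(b.composition)  # atom-by-atom identity
    assert a.mono_mass == pytest.approx(b.mono_mass, abs=1e-12)


def test_singleton_library_single_class():
    classes = isobaric_classes([Peptide("KESEEE", "amide")])
    assert len(classes) == 1 and classes[0].size == 1


def test_isobaric_partition_is_equivalence_relation(hexa_library, hexa_classes):
    # partition: every peptide in exactly one class, classes share one key
    seen = {}
    for cls in hexa_classes:
        for p in cls.members:
            assert p.sequence not in seen
            seen[p.sequence] = cls.key
            assert dict(p.composition) == dict(cls.members[0].composition)
    assert len(seen) == len(hexa_library)


@pytest.mark.parametrize("tolerance", [1e-6, 0.01, 0.5])
def test_exact_classes_nest_inside_tolerance_classes(hexa_library, hexa_classes, tolerance):
    tol_classes = isobaric_classes(hexa_library, "mass-tolerance", tolerance=tolerance)
    membership = {p.sequence: i for i, c in enumerate(tol_classes) for p in c.members}
    for cls in hexa_classes:
        assert len({membership[p.sequence] for p in cls.members}) == 1


def test_negative_tolerance_rejected(hexa_library):
    with pytest.raises(LibraryError):
        isobaric_classes(hexa_library, "mass-tolerance", tolerance=-0.1)


def test_peak_assignment(hexa_classes):
    peaks = [MassPeak(750.28, 100.0), MassPeak(2000.0, 10.0), MassPeak(763.35, 50.0)]
    assigned = assign_peaks(peaks, hexa_classes, tolerance=0.5)
    assert len(assigned[0].classes) == 1 and assigned[0].classes[0].size == 6
    assert not assigned[1].assigned
    assert [p.label for p in assigned[2].candidates] == ["KETEEE-NH2"]
    assert assigned[2].mass_error < 0.01


def test_enrichment_identical_runs_give_unit_ratios(hexa_classes):
    peaks = [
        MassPeak(peptide_mass(c.members[0], adduct="protonated"), 10.0 * c.size)
        for c in hexa_classes
    ]
    table = enrichment_score(peaks, peaks, peaks, hexa_classes)
    kept = table[~table["excluded"]]
    assert np.allclose(kept["enrichment"], 1.0)
    assert not table["unspecific"].any()


def _pulldown_table(hexa_classes, noise_sd, seed):
    cfg = synth.preset("peaks/pulldown", seed=seed)
    cfg.noise_sd = noise_sd
    data = synth.generate(cfg)

    def peaks(run):
        frame = data.tables[run]
        return [MassPeak(r.mz, r.intensity, run) for r in frame.itertuples()]

    return enrichment_score(peaks("library"), peaks("eluent"), peaks("control"), hexa_classes)


def test_enrichment_ranks_tripled_class_top_without_noise(hexa_classes):
    table = _pulldown_table(hexa_classes, noise_sd=0.0, seed=0)
    top = table.iloc[0]
    assert "EETEED-NH2" in top["members"] and top["n_members"] == 6
    assert top["enrichment"] > table.iloc[1]["enrichment"]


def test_enrichment_surfaces_enriched_set_and_excludes_sticky(hexa_classes):
    table = _pulldown_table(hexa_classes, noise_sd=0.05, seed=3)
    top3 = ";".join(table.head(3)["members"])
    for seq in ("EETEED-NH2", "KETEEE-NH2", "EETEEE-NH2"):
        assert seq in top3
    sticky = table[table["members"].str.contains("GDTDDD")]
    assert bool(sticky["excluded"].all())  # control-enriched class is dropped
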