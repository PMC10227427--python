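"""In-silico digestion, PAI/emPAI and proteome mass coverage."""

from __future__ import annotations

import math
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from pyteomics import mass as pmass
from pyteomics import parser as pparser

from tmtdyn.abundance_empai import (
    EmpaiTable,
    PROTON_MASS,
    build_empai_table,
    count_observable,
    digest,
    empai,
    mass_coverage,
    peptide_mass,
    protein_content,
)
from tmtdyn.exceptions import UndefinedStatisticError, ValidationError
from tmtdyn.io_formats import ProteinRecord, ProteomeDB
from tmtdyn.synthetic_data import simulate_fasta


def regex_digest_oracle(sequence: str, missed: int = 0) -> set[str]:
    """Independent cleavage-site enumeration via regex lookaround."""
    sites = [m.start() for m in re.finditer(r"(?<=[KR])(?!P)", sequence)]
    bounds = [0, *[s for s in sites if s < len(sequence)], len(sequence)]
    frags = [sequence[bounds[i]: bounds[i + 1]] for i in range(len(bounds) - 1)]
    out = set()
    for m in range(missed + 1):
        for i in range(len(frags) - m):
            out.add("".join(frags[i: i + m + 1]))
    return out


class TestDigest:
    def test_proline_blocks_cleavage(self):
        assert digest("AKRPK") == ["AK", "RPK"]

    def test_no_cleavage_sites(self):
        assert digest("MAGICW") == ["MAGICW"]

    def test_missed_cleavage_windows(self):
        assert digest("AKCK", missed=1) == ["AK", "CK", "AKCK"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            digest("")

    @given(st.text(alphabet="ACDKRPGW", min_size=1, max_size=40))
    def test_fully_cleaved_peptides_reconstruct_parent(self, seq):
        assert "".join(digest(seq)) == seq

    @pytest.mark.parametrize("missed", [0, 1, 2])
    def test_matches_regex_oracle_on_random_sequences(self, missed):
        rng = np.random.default_rng(17)
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(1000):
            seq = "".join(rng.choice(residues, size=rng.integers(1, 60)))
            assert set(digest(seq, missed=missed)) == regex_digest_oracle(seq, missed)

    def test_matches_pyteomics_cleave(self):
        # same Keil rule expressed as a cleave regex; pyteomics does the
        # missed-cleavage windowing independently of our implementation
        rule = r"[KR](?!P)"
        rng = np.random.default_rng(23)
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            seq = "".join(rng.choice(residues, size=rng.integers(5, 80)))
            ours = set(digest(seq, missed=2))
            ref = pparser.cleave(seq, rule, missed_cleavages=2, min_length=1)
            assert ours == set(ref)


class TestCountObservable:
    def test_empty_list(self):
        assert count_observable([]) == 0

    def test_unbounded_window_counts_everything(self):
        assert count_observable(["GGGGG"], (1e-6, 1e9), charges=(1,)) == 1

    def test_brute_force_mass_charge_enumeration(self):
        rng = np.random.default_rng(31)
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peptides = ["".join(rng.choice(residues, size=rng.integers(3, 40)))
                    for _ in range(200)]
        expected = 0
        for pep in dict.fromkeys(peptides):
            m = pmass.fast_mass(pep)
            ok = False
            for z in (2, 3):
                mz = (m + z * PROTON_MASS) / z
                if 385 <= mz <= 1250:
                    ok = True
            expected += ok
        assert count_observable(peptides, (385, 1250), (2, 3)) == expected

    def test_window_must_be_ordered(self):
        with pytest.raises(ValidationError):
            count_observable(["AK"], (1250, 385))


class TestEmpai:
    def test_zero_observed(self):
        assert empai(0, 10) == (0.0, 0.0)

    def test_full_coverage(self):
        pai, em = empai(10, 10)
        assert pai == 1.0
        assert em == pytest.approx(9.0)

    def test_fractional_pai_cross_checked_by_log_inverse(self):
        pai, em = empai(3, 17)
        assert em == pytest.approx(10 ** (3 / 17) - 1, rel=1e-12)
        assert math.log10(em + 1) == pytest.approx(pai, rel=1e-12)

    def test_undefined_for_zero_observable(self):
        with pytest.raises(UndefinedStatisticError):
            empai(3, 0)

    def test_strictly_increasing_in_observed(self):
        values = [empai(k, 12)[1] for k in range(13)]
        assert all(b > a for a, b in zip(values, values[1:]))


def make_empai_table(rows):
    """rows: {accession: (empai, mw_average_da)}"""
    frame = pd.DataFrame(
        {
            "n_observed": 1,
            "n_observable": 1,
            "pai": [np.log10(e + 1) for e, _ in rows.values()],
            "empai": [e for e, _ in rows.values()],
            "mw": [m for _, m in rows.values()],
        },
        index=pd.Index(rows, name="accession"),
    )
    total = frame["empai"].sum()
    frame["molar_fraction"] = frame["empai"] / total
    frame["mass_fraction"] = frame["empai"] * frame["mw"] / (frame["empai"] * frame["mw"]).sum()
    return EmpaiTable(frame)


def make_db(mws):
    records = {
        acc: ProteinRecord(acc, acc, "ACDEFGHIK", mw, mw) for acc, mw in mws.items()
    }
    return ProteomeDB(records)


class TestProteinContent:
    def test_single_protein(self):
        table = make_empai_table({"P1": (4.0, 20000.0)})
        assert protein_content(table, "molar")["P1"] == 1.0
        assert protein_content(table, "mass")["P1"] == 1.0

    def test_symmetry(self):
        table = make_empai_table({"P1": (2.0, 30000.0), "P2": (2.0, 30000.0)})
        assert protein_content(table, "molar").tolist() == [0.5, 0.5]
        assert protein_content(table, "mass").tolist() == [0.5, 0.5]

    def test_molar_vs_mass_weighting(self):
        table = make_empai_table({"A": (9.0, 10000.0), "B": (1.0, 90000.0)})
        molar = protein_content(table, "molar")
        mass = protein_content(table, "mass")
        assert molar["A"] == pytest.approx(0.9)
        assert molar["B"] == pytest.approx(0.1)
        assert mass["A"] == pytest.approx(0.5)
        assert mass["B"] == pytest.approx(0.5)

    def test_all_zero_is_undefined(self):
        table = make_empai_table({"A": (0.0, 1.0), "B": (0.0, 1.0)})
        with pytest.raises(UndefinedStatisticError):
            protein_content(table, "molar")


class TestMassCoverage:
    def test_complete_identification(self):
        table = make_empai_table({"A": (2.0, 10000.0), "B": (1.0, 10000.0)})
        db = make_db({"A": 10000.0, "B": 10000.0})
        assert mass_coverage(table, db) == pytest.approx(1.0)

    def test_floored_unidentified_toy_case(self):
        table = make_empai_table({"A": (9.0, 10000.0), "B": (1.0, 10000.0)})
        db = make_db({"A": 10000.0, "B": 10000.0, "C": 10000.0})
        assert mass_coverage(table, db) == pytest.approx(10.0 / 11.0)

    def test_single_identified_among_hundred(self):
        table = make_empai_table({"A": (5.0, 10000.0)})
        db = make_db({f"X{i}": 10000.0 for i in range(99)} | {"A": 10000.0})
        assert mass_coverage(table, db) == pytest.approx(0.01)

    def test_unknown_identified_accession_rejected(self):
        table = make_empai_table({"A": (5.0, 10000.0)})
        with pytest.raises(ValidationError):
            mass_coverage(table, make_db({"B": 10000.0}))

    def test_growing_database_never_increases_coverage(self):
        table = make_empai_table({"A": (3.0, 10000.0), "B": (0.5, 20000.0)})
        rng = np.random.default_rng(9)
        mws = {"A": 10000.0, "B": 20000.0}
        previous = mass_coverage(table, make_db(mws))
        assert 0 < previous <= 1
        for i in range(10):
            mws[f"U{i}"] = float(rng.uniform(5000, 120000))
            current = mass_coverage(table, make_db(mws))
            assert current <= previous + 1e-12
            previous = current


class TestBuildEmpaiTable:
    def test_fraction_columns_sum_to_one(self):
        db = simulate_fasta(20, mean_length=250, seed=5)
        observed = {acc: int(k) for k, acc in enumerate(db.accessions(), start=1)}
        table = build_empai_table(observed, db)
        assert table.frame["molar_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table.frame["mass_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_pai_recovers_observed_fraction(self):
        """Observing a fixed fraction f of observable peptides gives PAI ≈ f."""
        db = simulate_fasta(40, mean_length=500, seed=6)
        f = 0.4
        observed = {}
        for acc in db.accessions():
            peptides = digest(db[acc].sequence)
            n_obsbl = count_observable(peptides)
            observed[acc] = max(1, round(f * n_obsbl))
        table = build_empai_table(observed, db)
        assert float(table.frame["pai"].mean()) == pytest.approx(f, abs=0.05)
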