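"""emPAI absolute protein abundance from in-silico tryptic digestion.

The protein abundance index PAI is the number of distinct observed peptides
divided by the number of *observable* peptides — in-silico digestion products
whose mass-to-charge falls inside the instrument's acquisition window for at
least one allowed charge state.  Its exponentially modified form,
emPAI = 10^PAI − 1, is proportional to protein molar amount, so molar and
mass fractions of the expressed proteome follow by normalization:

    molar_i = emPAI_i / Σ emPAI,     mass_i = emPAI_i·MW_i / Σ emPAI·MW.

The captured fraction of the expressed protein mass is estimated by assigning
every database protein absent from the identified set the lowest observed
emPAI and computing the identified share of Σ emPAI·MW.

Digestion uses the trypsin rule (cleave C-terminal to K/R, blocked by a
following P — the Keil rule; the proline block can be disabled).  Peptide
masses are monoisotopic; protein MW for mass fractions is the average mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .exceptions import UndefinedStatisticError, ValidationError
from .io_formats import CANONICAL_RESIDUES, ProteomeDB

PROTON_MASS = 1.00727646688  # Da

#: Default instrument acquisition window (m/z) and charge states considered.
DEFAULT_MZ_WINDOW = (385.0, 1250.0)
DEFAULT_CHARGES = (2, 3)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def digest(
    sequence: str,
    missed: int = 0,
    block_proline: bool = True,
) -> list[str]:
    """In-silico tryptic digestion.

    Cleaves C-terminal to K/R, by default not when the next residue is P.
    With ``missed`` > 0 additionally emits all concatenations of up to
    ``missed``+1 adjacent fragments.  The fully cleaved peptides (missed=0)
    concatenate, in order, to the parent sequence.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    if missed < 0:
        raise ValidationError("missed cleavages must be >= 0")
    seq = sequence.upper()
    cuts = [
        i + 1
        for i, res in enumerate(seq[:-1])
        if res in "KR" and not (block_proline and seq[i + 1] == "P")
    ]
    bounds = [0, *cuts, len(seq)]
    fragments = [seq[bounds[i]: bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides: list[str] = []
    for span in range(min(missed, len(fragments) - 1) + 1):
        for start in range(len(fragments) - span):
            peptides.append("".join(fragments[start: start + span + 1]))
    return peptides


def peptide_mass(peptide: str) -> float:
    """Neutral monoisotopic mass; NaN for non-canonical residues."""
    if set(peptide) <= CANONICAL_RESIDUES:
        return float(_pmass.fast_mass(peptide))
    return float("nan")


def count_observable(
    peptides: Iterable[str],
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> int:
    """Count distinct peptides observable within the acquisition window.

    A peptide of neutral monoisotopic mass M is observable when at least one
    charge state z satisfies ``lo <= (M + z·proton)/z <= hi``.  Peptides with
    non-canonical residues (undefined mass) are never counted.
    """
    lo, hi = mz_window
    if not lo < hi:
        raise ValidationError("mass window min must be < max")
    count = 0
    for pep in dict.fromkeys(peptides):
        m = peptide_mass(pep)
        if np.isnan(m):
            continue
        if any(lo <= (m + z * PROTON_MASS) / z <= hi for z in charges):
            count += 1
    return count


# ---------------------------------------------------------------------------
# PAI / emPAI
# ---------------------------------------------------------------------------

def empai(n_observed: int, n_observable: int) -> tuple[float, float]:
    """(PAI, emPAI) from observed and observable peptide counts."""
    if n_observable < 1:
        raise UndefinedStatisticError("emPAI undefined for n_observable = 0")
    if n_observed < 0:
        raise ValidationError("n_observed must be >= 0")
    pai = n_observed / n_observable
    return pai, 10.0 ** pai - 1.0


@dataclass
class EmpaiTable:
    """Per-protein absolute abundance estimates.

    ``frame`` columns: n_observed, n_observable, pai, empai, mw (average Da),
    molar_fraction, mass_fraction; indexed by accession.  Molar and mass
    fractions each sum to 1 over the table.
    """

    frame: pd.DataFrame


def build_empai_table(
    observed: Mapping[str, Iterable[str] | int],
    db: ProteomeDB,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
    charges: Sequence[int] = DEFAULT_CHARGES,
    missed: int = 0,
) -> EmpaiTable:
    """emPAI table for the identified proteins.

    ``observed`` maps accession to either a collection of identified peptide
    sequences (counted as distinct sequences) or directly to a count.  All
    accessions must be present in ``db``; observable counts come from
    in-silico digestion of the database sequence.
    """
    rows = []
    for accession, obs in observed.items():
        if accession not in db:
            raise ValidationError(f"identified accession {accession!r} not in database")
        record = db[accession]
        n_obs = obs if isinstance(obs, (int, np.integer)) else len(set(obs))
        peptides = digest(record.sequence, missed=missed)
        n_obsbl = count_observable(peptides, mz_window, charges)
        if n_obsbl < 1:
            raise UndefinedStatisticError(
                f"{accession}: no observable peptides in window {mz_window}"
            )
        pai, em = empai(int(n_obs), n_obsbl)
        rows.append(
            {
                "accession": accession,
                "n_observed": int(n_obs),
                "n_observable": n_obsbl,
                "pai": pai,
                "empai": em,
                "mw": record.mw_average,
            }
        )
    frame = pd.DataFrame(rows).set_index("accession")
    total = frame["empai"].sum()
    total_mass = (frame["empai"] * frame["mw"]).sum()
    frame["molar_fraction"] = frame["empai"] / total if total > 0 else np.nan
    frame["mass_fraction"] = (
        frame["empai"] * frame["mw"] / total_mass if total_mass > 0 else np.nan
    )
    return EmpaiTable(frame)


def protein_content(table: EmpaiTable, mode: str = "molar") -> pd.Series:
    """Normalized per-protein fractions of the expressed proteome.

    ``mode='molar'`` weights by emPAI alone; ``mode='mass'`` by emPAI·MW.
    """
    if table.frame.empty:
        raise ValidationError("empty emPAI table")
    if mode == "molar":
        weights = table.frame["empai"]
    elif mode == "mass":
        weights = table.frame["empai"] * table.frame["mw"]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    total = weights.sum()
    if total <= 0:
        raise UndefinedStatisticError("all emPAI values are zero")
    return weights / total


def mass_coverage(
    identified: EmpaiTable,
    full_db: ProteomeDB,
    weighting: str = "mass",
) -> float:
    """Captured fraction of the expressed proteome.

    Every database protein absent from the identified set is assigned the
    lowest observed emPAI (a conservative floor); the captured fraction is
    the identified share of Σ emPAI·MW (``weighting='mass'``) or of Σ emPAI
    (``weighting='molar'``).
    """
    frame = identified.frame
    if frame.empty:
        raise ValidationError("empty identified table")
    unknown = [a for a in frame.index if a not in full_db]
    if unknown:
        raise ValidationError(f"identified accessions not in database: {unknown}")
    floor = float(frame["empai"].min())
    missing = [a for a in full_db.accessions() if a not in frame.index]
    if weighting == "mass":
        got = float((frame["empai"] * frame["mw"]).sum())
        rest = floor * float(np.nansum([full_db[a].mw_average for a in missing]))
    elif weighting == "molar":
        got = float(frame["empai"].sum())
        rest = floor * len(missing)
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    total = got + rest
    if total <= 0:
        raise UndefinedStatisticError("total emPAI weight is zero")
    return got / total
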