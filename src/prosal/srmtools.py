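"""Targeted (SRM) assay design and quantification.

Covers proteotypic peptide selection from an in-silico tryptic digest,
monoisotopic precursor and y/b fragment m/z calculation with C-terminal
heavy-isotope labels, light/heavy ratio quantification of per-replicate
peak areas, and the nested-ANOVA / Mann–Whitney group comparison used for
technical-triplicate verification cohorts.

Mass constants are CODATA/IUPAC monoisotopic values; the heavy-label mass
shifts for [13C6,15N2]-lysine and [13C6,15N4]-arginine are derived from the
isotope mass differences rather than hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .formats import AMINO_ACIDS, ProteinRecord, proteome_index

logger = logging.getLogger("prosal")

# ---------------------------------------------------------------------------
# Mass tables
# ---------------------------------------------------------------------------

#: monoisotopic residue masses (Da)
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276

#: isotope mass differences used to derive heavy-label shifts
C13_MINUS_C12 = 1.003355
N15_MINUS_N14 = 0.997035

#: mass shift of [13C6,15N2]-lysine and [13C6,15N4]-arginine
HEAVY_K = 6 * C13_MINUS_C12 + 2 * N15_MINUS_N14
HEAVY_R = 6 * C13_MINUS_C12 + 4 * N15_MINUS_N14

#: fixed-modification delta for carbamidomethylated cysteine
CARBAMIDOMETHYL_C = 57.02146

MOD_DELTAS = {"carbamidomethyl-C": CARBAMIDOMETHYL_C}


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up, the rounding used in printed transition lists."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r} at position {i}")


def _mod_mass(sequence: str, mods: tuple[str, ...]) -> float:
    delta = 0.0
    for mod in mods:
        if mod not in MOD_DELTAS:
            raise ValueError(f"unknown modification {mod!r}")
        if mod == "carbamidomethyl-C":
            delta += MOD_DELTAS[mod] * sequence.count("C")
    return delta


def peptide_mass(sequence: str, mods: tuple[str, ...] = (), heavy: bool = False) -> float:
    """Neutral monoisotopic peptide mass (Da)."""
    _check_sequence(sequence)
    mass = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER
    mass += _mod_mass(sequence, mods)
    if heavy:
        mass += _heavy_delta(sequence)
    return mass


def _heavy_delta(sequence: str) -> float:
    if sequence.endswith("K"):
        return HEAVY_K
    if sequence.endswith("R"):
        return HEAVY_R
    raise ValueError("heavy label requires a C-terminal K or R")


def peptide_mz(sequence: str, charge: int, mods: tuple[str, ...] = (),
               heavy: bool = False) -> float:
    """Precursor m/z: (M + z·proton) / z, monoisotopic."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(sequence, mods, heavy) + charge * PROTON) / charge


def fragment_mz(sequence: str, series: str, index: int, charge: int = 1,
                mods: tuple[str, ...] = (), heavy: bool = False) -> float:
    """y/b fragment-ion m/z.

    y_k carries the C-terminal k residues plus water; b_k the N-terminal k
    residues.  A C-terminal heavy label therefore shifts y ions (and never
    b ions).
    """
    _check_sequence(sequence)
    if series not in ("y", "b"):
        raise ValueError(f"unknown ion series {series!r}")
    if not 1 <= index <= len(sequence) - 1:
        raise ValueError(f"fragment index {index} out of range for "
                         f"{len(sequence)}-residue peptide")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if series == "y":
        part = sequence[-index:]
        mass = sum(RESIDUE_MASS[aa] for aa in part) + WATER
        mass += _mod_mass(part, mods)
        if heavy:
            mass += _heavy_delta(sequence)
    else:
        part = sequence[:index]
        mass = sum(RESIDUE_MASS[aa] for aa in part)
        mass += _mod_mass(part, mods)
    return (mass + charge * PROTON) / charge


def heavy_transition_mz(sequence: str, series: str, index: int,
                        charge: int = 1, mods: tuple[str, ...] = ()) -> float:
    """Fragment m/z of the heavy-labeled standard (C-terminal K/R label)."""
    _heavy_delta(sequence)  # validates the terminal residue
    return fragment_mz(sequence, series, index, charge, mods, heavy=True)


# ---------------------------------------------------------------------------
# Proteotypic peptide selection
# ---------------------------------------------------------------------------

def digest_tryptic(sequence: str, no_cut_before_proline: bool = True) -> list[str]:
    """Fully tryptic in-silico digest: cleave after K/R (optionally not
    before P), zero missed cleavages."""
    peptides = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and i + 1 < len(sequence):
            if no_cut_before_proline and sequence[i + 1] == "P":
                continue
            peptides.append(sequence[start:i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return peptides


def select_proteotypic(
    accession: str,
    proteome: list[ProteinRecord],
    max_len: int = 20,
    min_len: int = 6,
    no_cut_before_proline: bool = True,
) -> list[str]:
    """Candidate surrogate peptides for one protein.

    Fully tryptic peptides shorter than ``max_len`` residues, ending in K/R
    (the protein's C-terminal peptide exempt), and occurring as a substring
    of exactly one proteome protein.
    """
    index = proteome_index(proteome)
    if accession not in index:
        raise ValueError(f"{accession} not in proteome")
    protein = index[accession]
    candidates = []
    for pep in digest_tryptic(protein.sequence, no_cut_before_proline):
        if not (min_len <= len(pep) < max_len):
            continue
        if not pep.endswith(("K", "R")) and not protein.sequence.endswith(pep):
            continue
        owners = {rec.accession for rec in proteome if pep in rec.sequence}
        if owners == {accession}:
            candidates.append(pep)
    return candidates


def build_transition_table(
    targets: dict[str, list[str]],
    precursor_charge: int = 2,
    fragment_indices: tuple[int, ...] = (3, 4, 5),
    with_heavy: bool = True,
) -> pd.DataFrame:
    """Transition list for ``protein -> [peptides]`` with y-ion fragments.

    Fragment indices default to y3–y5; indices outside a peptide's range are
    skipped.  Heavy rows require the C-terminal K/R label.
    """
    rows = []
    for protein, peptides in targets.items():
        for pep in peptides:
            channels = ("light", "heavy") if with_heavy else ("light",)
            for channel in channels:
                heavy = channel == "heavy"
                rows.append({
                    "protein": protein, "peptide": pep,
                    "precursor_charge": precursor_charge,
                    "fragment": "precursor", "channel": channel,
                    "mz": round_half_up(
                        peptide_mz(pep, precursor_charge, heavy=heavy), 4),
                })
                for idx in fragment_indices:
                    if not 1 <= idx <= len(pep) - 1:
                        continue
                    rows.append({
                        "protein": protein, "peptide": pep,
                        "precursor_charge": precursor_charge,
                        "fragment": f"y{idx}", "channel": channel,
                        "mz": round_half_up(
                            fragment_mz(pep, "y", idx, 1, heavy=heavy), 4),
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SRM quantification and statistics
# ---------------------------------------------------------------------------

def quantify_srm(measurements: pd.DataFrame) -> pd.DataFrame:
    """Light/heavy ratios per sample × replicate × peptide.

    The ratio is Σ(light areas)/Σ(heavy areas) over the peptide's
    transitions within one replicate; replicates whose heavy areas are all
    zero are excluded with a log message.  Replicates are retained (not
    averaged) so the nested group test sees the technical structure.
    """
    required = {"sample_id", "group", "replicate", "peptide",
                "light_area", "heavy_area"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns {sorted(missing)}")
    rows = []
    grouped = measurements.groupby(["peptide", "sample_id", "replicate"],
                                   sort=True)
    for (peptide, sample, replicate), block in grouped:
        heavy = float(block["heavy_area"].sum())
        if heavy <= 0:
            logger.warning("replicate excluded (zero heavy signal): %s %s rep %s",
                           peptide, sample, replicate)
            continue
        rows.append({
            "peptide": peptide, "sample_id": sample,
            "group": block["group"].iloc[0], "replicate": replicate,
            "ratio": float(block["light_area"].sum()) / heavy,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NestedAnovaResult:
    f_statistic: float
    p_value: float
    df_group: int
    df_samples: int
    df_error: int
    zero_variance: bool = False


def nested_anova(ratios: pd.DataFrame, value: str = "ratio") -> NestedAnovaResult:
    """Two-level nested ANOVA: samples within groups, replicates within
    samples; the group effect is tested against the among-sample
    mean square.  With a single replicate per sample this collapses to the
    one-way ANOVA on sample values.
    """
    y = ratios[value].to_numpy(float)
    grand = y.mean()
    groups = ratios.groupby("group")
    ss_group = 0.0
    ss_samples = 0.0
    ss_error = 0.0
    n_samples = 0
    for _, gblock in groups:
        gmean = gblock[value].mean()
        ss_group += len(gblock) * (gmean - grand) ** 2
        for _, sblock in gblock.groupby("sample_id"):
            smean = sblock[value].mean()
            n_samples += 1
            ss_samples += len(sblock) * (smean - gmean) ** 2
            ss_error += ((sblock[value] - smean) ** 2).sum()
    n_groups = groups.ngroups
    df_group = n_groups - 1
    df_samples = n_samples - n_groups
    df_error = len(y) - n_samples
    if df_group < 1 or df_samples < 1:
        raise ValueError("nested ANOVA needs >= 2 groups and >= 2 samples per group")
    ms_group = ss_group / df_group
    ms_samples = ss_samples / df_samples
    if ms_samples == 0:
        zero = True
        p = 1.0 if ms_group == 0 else 0.0
        f = np.inf if ms_group > 0 else 0.0
    else:
        zero = False
        f = ms_group / ms_samples
        p = float(stats.f.sf(f, df_group, df_samples))
    return NestedAnovaResult(float(f), float(p), df_group, df_samples,
                             df_error, zero)


def srm_group_compare(ratios: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-peptide nested ANOVA and Mann–Whitney group comparison.

    The nested ANOVA accounts for technical replicates within samples; the
    Mann–Whitney test compares the two groups on per-sample replicate
    means.  Returns one row per peptide.
    """
    out = []
    for peptide, block in ratios.groupby("peptide"):
        groups = block["group"].unique()
        if len(groups) != 2:
            raise ValueError(f"{peptide}: need exactly 2 groups, got {list(groups)}")
        per_sample = (block.groupby(["group", "sample_id"])["ratio"]
                      .mean().reset_index())
        sizes = per_sample.groupby("group").size()
        if (sizes < 2).any():
            raise ValueError(f"{peptide}: need >= 2 samples per group")
        nested = nested_anova(block)
        a = per_sample.loc[per_sample["group"] == groups[0], "ratio"]
        b = per_sample.loc[per_sample["group"] == groups[1], "ratio"]
        mw = stats.mannwhitneyu(a, b, alternative="two-sided")
        out.append({
            "peptide": peptide,
            "nested_anova_F": nested.f_statistic,
            "nested_anova_p": nested.p_value,
            "mann_whitney_U": float(mw.statistic),
            "mann_whitney_p": float(mw.pvalue),
            "median_ratio_" + groups[0]: float(a.median()),
            "median_ratio_" + groups[1]: float(b.median()),
            "significant": bool(nested.p_value <= alpha
                                and mw.pvalue <= alpha),
        })
    return pd.DataFrame(out)
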