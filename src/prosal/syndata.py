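"""Synthetic peptidome generator with known ground truth.

Emulates the structure of a two-group (pN0/pN+) endogenous-peptidomics
study: a proteome of random sequences, peptides released by planted
proteases with defined cleavage specificity plus background peptides cut at
random positions, log-normal label-free intensities with a group effect on a
differential subset, missing-at-random cells, quality scores, and clinical
covariates correlated with selected peptides through a shared latent
variable.  Every planted fact (generating protease, differential status,
clinical linkage) is recorded in :class:`PlantedTruth` so downstream stages
can be tested against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .formats import (
    AMINO_ACIDS,
    GROUP_NEGATIVE,
    GROUP_POSITIVE,
    ClinicalTable,
    PeptideQuantTable,
    ProteinQuantTable,
    ProteinRecord,
    ProteaseRule,
)

__all__ = [
    "ClinicalFeatureSpec",
    "SyntheticConfig",
    "PlantedPeptide",
    "PlantedTruth",
    "default_config",
    "generate_proteome",
    "plant_digest",
    "simulate_quant",
    "simulate_study",
    "simulate_panel",
    "simulate_protein_table",
    "simulate_srm_measurements",
]


@dataclass(frozen=True)
class ClinicalFeatureSpec:
    name: str
    kind: str  # "binary" or "ordinal"
    linked_peptide_count: int
    target_correlation: float

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal"):
            raise ValueError(f"unknown clinical feature kind {self.kind!r}")
        if not -1 < self.target_correlation < 1:
            raise ValueError("target_correlation must lie in (-1, 1)")


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic peptidome.

    Defaults emulate the discovery cohort: 12 pN0 vs 13 pN+ samples, a few
    hundred quantifiable peptides over tens of proteins, log2 baselines
    uniform on [20, 30] (a six-order-of-magnitude dynamic range), a
    differential subset shifted by ``effect_log2fc`` in the pN+ group, and
    binary clinical covariates tied to a handful of peptides.
    """

    n_proteins: int = 40
    protein_length_range: tuple[int, int] = (150, 400)
    residue_background: np.ndarray | None = None  # None = uniform over 20
    planted_proteases: list[tuple[ProteaseRule, int]] = field(default_factory=list)
    peptide_length_range: tuple[int, int] = (7, 30)
    background_fraction: float = 0.5
    n_samples_per_group: tuple[int, int] = (12, 13)
    effect_log2fc: float = 2.0
    cv_intensity: float = 0.3
    missing_rate: float = 0.10
    frac_differential: float = 0.11
    frac_low_quality: float = 0.30
    quality_threshold: float = 8.0
    clinical_features: list[ClinicalFeatureSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        bg = self.residue_background
        if bg is None:
            bg = np.full(20, 1.0 / 20.0)
        bg = np.asarray(bg, dtype=float)
        if bg.shape != (20,):
            raise ValueError("residue_background must be a 20-vector")
        if (bg < 0).any():
            raise ValueError("residue_background has negative frequencies")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("residue_background must sum to 1 ± 1e-9")
        self.residue_background = bg
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if min(self.n_samples_per_group) < 2:
            raise ValueError("need at least 2 samples per group")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid protein_length_range")

    @property
    def sigma_log2(self) -> float:
        """Log2-scale standard deviation implied by ``cv_intensity``."""
        return float(np.sqrt(np.log(1.0 + self.cv_intensity ** 2)) / np.log(2.0))


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-condition config with two planted proteases and two covariates."""
    cathepsin_d = ProteaseRule("CTSD", {"P1": frozenset("FWYL")},
                               evidence="planted")
    gln_endopeptidase = ProteaseRule("QGEP", {"P1": frozenset("Q"),
                                              "P1'": frozenset("G")},
                                     evidence="planted")
    return SyntheticConfig(
        planted_proteases=[(cathepsin_d, 120), (gln_endopeptidase, 120)],
        clinical_features=[
            ClinicalFeatureSpec("extracapsular_extension", "binary", 3, 0.8),
            ClinicalFeatureSpec("perineural_invasion", "binary", 3, 0.8),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def generate_proteome(config: SyntheticConfig) -> list[ProteinRecord]:
    """Draw ``n_proteins`` i.i.d. sequences from the residue background."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=config.residue_background))
        records.append(ProteinRecord(
            accession=f"SYN{i + 1:04d}",
            sequence=seq,
            description=f"synthetic protein {i + 1}",
        ))
    return records


# ---------------------------------------------------------------------------
# Planted digest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPeptide:
    peptide_id: str
    sequence: str
    accession: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    protease_id: str | None  # None for background peptides
    side: str | None = None  # which boundary coincides with the planted cut


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside the synthetic tables."""

    protease_of: dict[str, str | None] = field(default_factory=dict)
    locations: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    differential: dict[str, float] = field(default_factory=dict)  # id -> true log2fc
    clinical_links: dict[str, list[str]] = field(default_factory=dict)
    clinical_correlation: dict[str, float] = field(default_factory=dict)

    def is_differential(self, peptide_id: str) -> bool:
        return self.differential.get(peptide_id, 0.0) != 0.0

    def to_json(self, path) -> None:
        payload = {
            "protease_of": self.protease_of,
            "locations": {k: list(v) for k, v in self.locations.items()},
            "differential": self.differential,
            "clinical_links": self.clinical_links,
            "clinical_correlation": self.clinical_correlation,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def plant_digest(
    proteome: list[ProteinRecord],
    planted_proteases: list[tuple[ProteaseRule, int]],
    peptide_length_range: tuple[int, int] = (7, 30),
    background_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[PlantedPeptide], PlantedTruth]:
    """Release peptides whose boundaries sit at rule-admissible cut sites.

    Each planted event picks a rule-satisfying bond in the proteome and emits
    a peptide whose N- or C-terminal boundary (chosen at random) coincides
    with it.  ``background_fraction`` × (planted count) extra peptides are
    cut at uniformly random positions.  Coordinates are 1-based inclusive.
    """
    rng = np.random.default_rng(seed)
    lo, hi = peptide_length_range
    peptides: list[PlantedPeptide] = []
    truth = PlantedTruth()

    site_index: list[tuple[ProteaseRule, int, list[tuple[int, int]]]] = []
    for rule, events in planted_proteases:
        sites = [(pi, c) for pi, rec in enumerate(proteome)
                 for c in rule.cut_sites(rec.sequence)]
        if not sites:
            raise ValueError(
                f"no position in the proteome satisfies rule {rule.describe()}")
        site_index.append((rule, events, sites))

    counter = 0

    def _emit(accession: str, seq: str, start: int, end: int,
              protease_id: str | None, side: str | None) -> None:
        nonlocal counter
        counter += 1
        pid = f"pep{counter:04d}"
        peptides.append(PlantedPeptide(
            peptide_id=pid, sequence=seq[start - 1:end], accession=accession,
            start=start, end=end, protease_id=protease_id, side=side))
        truth.protease_of[pid] = protease_id
        truth.locations[pid] = (accession, start, end)

    for rule, events, sites in site_index:
        for _ in range(events):
            pi, cut = sites[int(rng.integers(len(sites)))]
            rec = proteome[pi]
            length = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5:  # peptide starts at the cut (N-side event)
                start = cut + 1
                end = min(cut + length, len(rec.sequence))
                side = "N"
            else:  # peptide ends at the cut (C-side event)
                end = cut
                start = max(1, cut - length + 1)
                side = "C"
            if end - start + 1 < 4:
                continue  # too close to a protein terminus; skip this event
            _emit(rec.accession, rec.sequence, start, end, rule.protease_id, side)

    n_background = int(round(background_fraction * len(peptides)))
    for _ in range(n_background):
        rec = proteome[int(rng.integers(len(proteome)))]
        length = int(rng.integers(lo, hi + 1))
        if len(rec.sequence) <= length + 1:
            continue
        start = int(rng.integers(1, len(rec.sequence) - length + 1))
        _emit(rec.accession, rec.sequence, start, start + length - 1, None, None)

    for rule, _, _ in site_index:
        if not any(p.protease_id == rule.protease_id for p in peptides):
            raise ValueError(
                f"planted protease {rule.protease_id} generated no peptide")
    return peptides, truth


# ---------------------------------------------------------------------------
# Quantification and clinical covariates
# ---------------------------------------------------------------------------

def _sample_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    n0, n1 = config.n_samples_per_group
    neg = [f"pN0_{i + 1:02d}" for i in range(n0)]
    pos = [f"pNpos_{i + 1:02d}" for i in range(n1)]
    return neg, pos


def simulate_quant(
    peptides: list[PlantedPeptide],
    config: SyntheticConfig,
    truth: PlantedTruth | None = None,
) -> tuple[PeptideQuantTable, ClinicalTable, PlantedTruth]:
    """Simulate the label-free quant table and clinical covariates.

    Log2 intensities are Normal(baseline, σ) with per-peptide baselines
    uniform on [20, 30]; a ``frac_differential`` subset is shifted by
    ``effect_log2fc`` in the pN+ group; cells go missing independently at
    ``missing_rate``; quality scores place a ``frac_low_quality`` fraction
    below the quality threshold.  Clinical covariates are thresholded latent
    Gaussians shared with their linked peptides, so ``target_correlation``
    applies on the latent scale.
    """
    if not peptides:
        raise ValueError("no peptides to quantify")
    truth = truth if truth is not None else PlantedTruth()
    rng = np.random.default_rng(config.seed + 1)
    neg, pos = _sample_names(config)
    samples = neg + pos
    group_map = {s: GROUP_NEGATIVE for s in neg}
    group_map.update({s: GROUP_POSITIVE for s in pos})

    n = len(peptides)
    ids = [p.peptide_id for p in peptides]
    sigma = config.sigma_log2
    baselines = rng.uniform(20.0, 30.0, size=n)

    n_diff = int(round(config.frac_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False) if n_diff else np.array([], int)
    effects = np.zeros(n)
    effects[diff_idx] = config.effect_log2fc
    for i in diff_idx:
        truth.differential[ids[i]] = float(config.effect_log2fc)

    is_pos = np.array([group_map[s] == GROUP_POSITIVE for s in samples])
    log2 = (baselines[:, None]
            + np.outer(effects, is_pos.astype(float))
            + rng.normal(0.0, sigma, size=(n, len(samples))))

    # clinical covariates share a latent Gaussian with their linked peptides
    clin_cols: dict[str, np.ndarray] = {}
    linkable = [i for i in range(n)]
    used: set[int] = set()
    for feat in config.clinical_features:
        z = rng.normal(0.0, 1.0, size=len(samples))
        # target_correlation refers to the *coded* covariate; thresholding a
        # latent Gaussian attenuates the observed correlation (factor
        # sqrt(2/pi) for a median-split binary, ~0.89 for tercile ordinal),
        # so the latent link is strengthened accordingly, clipped at 0.99
        attenuation = np.sqrt(2.0 / np.pi) if feat.kind == "binary" else 0.890
        r = min(feat.target_correlation / attenuation, 0.99)
        gamma = sigma * r / np.sqrt(1.0 - r ** 2)
        candidates = [i for i in linkable if i not in used]
        k = min(feat.linked_peptide_count, len(candidates))
        chosen = rng.choice(len(candidates), size=k, replace=False)
        linked = [candidates[int(j)] for j in chosen]
        used.update(linked)
        for i in linked:
            log2[i] = log2[i] + gamma * z
        if feat.kind == "binary":
            values = (z > 0).astype(float)
        else:
            values = np.digitize(z, np.quantile(z, [1 / 3, 2 / 3])).astype(float)
        clin_cols[feat.name] = values
        truth.clinical_links[feat.name] = [ids[i] for i in linked]
        truth.clinical_correlation[feat.name] = r

    intensities = np.power(2.0, log2)
    if config.missing_rate > 0:
        mask = rng.random(size=intensities.shape) < config.missing_rate
        intensities[mask] = np.nan

    low = rng.random(n) < config.frac_low_quality
    thr = config.quality_threshold
    quality = np.where(low, rng.uniform(0.0, thr, size=n),
                       rng.uniform(thr, 20.0, size=n))

    index = pd.Index(ids, name="peptide_id")
    data = pd.concat(
        [
            pd.DataFrame(
                {
                    "sequence": [p.sequence for p in peptides],
                    "proteins": [p.accession for p in peptides],
                    "quality": np.round(quality, 3),
                },
                index=index,
            ),
            pd.DataFrame(intensities, index=index, columns=samples),
        ],
        axis=1,
    )

    clin = pd.DataFrame({"group": [group_map[s] for s in samples]},
                        index=pd.Index(samples, name="sample_id"))
    for name, values in clin_cols.items():
        clin[name] = values

    return (PeptideQuantTable(data=data, group_map=group_map),
            ClinicalTable(data=clin), truth)


def simulate_study(config: SyntheticConfig):
    """Full generator chain: proteome → planted digest → quant + clinical.

    Returns ``(proteome, peptides, quant, clinical, truth)``.
    """
    proteome = generate_proteome(config)
    planted = config.planted_proteases or default_config(config.seed).planted_proteases
    peptides, truth = plant_digest(
        proteome, planted,
        peptide_length_range=config.peptide_length_range,
        background_fraction=config.background_fraction,
        seed=config.seed,
    )
    quant, clinical, truth = simulate_quant(peptides, config, truth)
    return proteome, peptides, quant, clinical, truth


# ---------------------------------------------------------------------------
# Purpose-built simulators for downstream calibration checks
# ---------------------------------------------------------------------------

def simulate_panel(
    target_auc: float = 0.86,
    n_features: int = 5,
    n_per_group: tuple[int, int] = (100, 100),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate-normal feature panel calibrated to a combined AUC.

    For k independent standard-normal features with a common per-feature
    group shift d, the optimal linear combination separates the groups with
    AUC = Φ(d·√k / √2); the shift is therefore set to
    d = Φ⁻¹(AUC)·√2/√k in closed form, not tuned.
    """
    d = stats.norm.ppf(target_auc) * np.sqrt(2.0) / np.sqrt(n_features)
    rng = np.random.default_rng(seed)
    n0, n1 = n_per_group
    x0 = rng.normal(0.0, 1.0, size=(n0, n_features))
    x1 = rng.normal(d, 1.0, size=(n1, n_features))
    X = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    return X, y


def simulate_protein_table(
    n_proteases: int = 20,
    n_inhibitors: int = 32,
    n_other: int = 20,
    inhibitor_shift: float = -0.8,
    protease_shift: float = -0.2,
    n_samples_per_group: tuple[int, int] = (9, 5),
    cv_intensity: float = 0.3,
    n_reverse: int = 3,
    n_only_by_site: int = 3,
    seed: int = 0,
) -> ProteinQuantTable:
    """Protein-group LFQ table with class-level log2 shifts planted in pN+.

    Emulates the bottom-up companion data: protease inhibitors reduced on
    average in pN+ saliva, proteases mildly reduced, plus a few reverse /
    only-by-site rows that the post-search cleanup must drop.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + cv_intensity ** 2)) / np.log(2.0))
    n0, n1 = n_samples_per_group
    neg = [f"pN0_{i + 1:02d}" for i in range(n0)]
    pos = [f"pNpos_{i + 1:02d}" for i in range(n1)]
    samples = neg + pos
    group_map = {s: GROUP_NEGATIVE for s in neg}
    group_map.update({s: GROUP_POSITIVE for s in pos})

    classes = (["protease"] * n_proteases + ["protease_inhibitor"] * n_inhibitors
               + ["other"] * n_other)
    shifts = ([protease_shift] * n_proteases + [inhibitor_shift] * n_inhibitors
              + [0.0] * n_other)
    rows = []
    index = []
    is_pos = np.array([group_map[s] == GROUP_POSITIVE for s in samples], float)
    for i, (tag, shift) in enumerate(zip(classes, shifts)):
        baseline = rng.uniform(24.0, 32.0)
        log2 = baseline + shift * is_pos + rng.normal(0.0, sigma, len(samples))
        rows.append([False, False, tag] + list(np.power(2.0, log2)))
        index.append(f"PROT{i + 1:04d}")
    for i in range(n_reverse):
        base = rng.uniform(24.0, 32.0)
        vals = np.power(2.0, base + rng.normal(0.0, sigma, len(samples)))
        rows.append([True, False, "other"] + list(vals))
        index.append(f"REV{i + 1:03d}")
    for i in range(n_only_by_site):
        base = rng.uniform(24.0, 32.0)
        vals = np.power(2.0, base + rng.normal(0.0, sigma, len(samples)))
        rows.append([False, True, "other"] + list(vals))
        index.append(f"OBS{i + 1:03d}")

    data = pd.DataFrame(rows, columns=["is_reverse", "only_by_site", "class_tag"]
                        + samples, index=pd.Index(index, name="accession"))
    return ProteinQuantTable(data=data, group_map=group_map)


def simulate_srm_measurements(
    peptide_effects: dict[str, float] | None = None,
    n_per_group: tuple[int, int] = (14, 26),
    n_replicates: int = 3,
    n_transitions: int = 3,
    sample_cv: float = 0.25,
    replicate_cv: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate SRM light/heavy peak areas with nested replicate structure.

    Emulates the verification cohort: N0 vs N+ samples measured as technical
    triplicates against heavy-labeled internal standards.  ``peptide_effects``
    maps peptide sequence → true N+/N0 light/heavy-ratio fold change.
    """
    if peptide_effects is None:
        peptide_effects = {"FSVVYAK": 0.5}
    rng = np.random.default_rng(seed)
    n0, n1 = n_per_group
    rows = []
    samples = ([(f"S{i + 1:03d}", "N0") for i in range(n0)]
               + [(f"S{n0 + i + 1:03d}", "N+") for i in range(n1)])
    s_sig = np.sqrt(np.log(1 + sample_cv ** 2))
    r_sig = np.sqrt(np.log(1 + replicate_cv ** 2))
    for pep, effect in peptide_effects.items():
        for sample_id, grp in samples:
            base = 1.0 if grp == "N0" else effect
            sample_ratio = base * rng.lognormal(-s_sig ** 2 / 2, s_sig)
            for rep in range(1, n_replicates + 1):
                rep_ratio = sample_ratio * rng.lognormal(-r_sig ** 2 / 2, r_sig)
                for t in range(1, n_transitions + 1):
                    heavy = rng.lognormal(np.log(1e5), 0.2)
                    noise = rng.lognormal(-0.02 ** 2 / 2, 0.02)
                    rows.append({
                        "sample_id": sample_id, "group": grp, "replicate": rep,
                        "peptide": pep, "fragment": f"y{t + 2}",
                        "light_area": heavy * rep_ratio * noise,
                        "heavy_area": heavy,
                    })
    return pd.DataFrame(rows)
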