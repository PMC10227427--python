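"""Ground-truthed synthetic multi-plex TMT experiments and proteomes.

The generator emulates a batch-bioreactor proteome dynamics study: two yeast
strains (a control and a minimal-glycolysis mutant) grown aerobically (five
phases: ME, LE, ED, MD, MS) and anaerobically (four phases: ME, LE, ES, MS)
in biological triplicate, each sample measured as two technical replicates in
TMT10 plexes carrying two bridge channels.  The default layout produces 14
plexes — one per strain × anaerobic biological replicate (8 samples + 2
bridges) and eight plexes packing the 60 aerobic sample-channels — mirroring
the scale of real multi-plex designs.

Generative model, in order: (1) baseline abundance a_i ~ log-normal;
(2) true sample abundance = a_i × 2^(regulon log2 effect) for that
strain/condition/phase; (3) biological replicate effect: multiplicative
log-normal at the biological RSD; (4) plex batch factor and channel loading
factor: multiplicative log-normal; (5) technical noise: multiplicative
log-normal at the technical RSD; (6) bridge channels carry the configured
pool composition (arithmetic mean of the designated reference samples);
(7) missingness: per protein × plex Bernoulli with detection probability
logistic in log10 abundance (abundance-dependent, MNAR-lite — the dominant
mechanism in data-dependent acquisition; completely-at-random and no
missingness are available).  All randomness flows from one seed, so the same
configuration regenerates bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io_formats import (
    AccessionGeneMap,
    ChannelDesign,
    DESIGN_COLUMNS,
    PlexTable,
    ProteinRecord,
    ProteomeDB,
    sequence_masses,
)

TMT10_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
)

CANONICAL_20 = "ACDEFGHIKLMNPQRSTVWY"


def rsd_to_sigma_ln(rsd_percent: float) -> float:
    """Natural-log sigma of a log-normal with the given linear-scale RSD (%)."""
    cv = rsd_percent / 100.0
    return math.sqrt(math.log1p(cv * cv))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Regulon:
    """A protein subset with per-strain/condition/phase true log2 fold changes.

    ``effects`` maps (strain, condition, phase) — any coordinate may be None
    as a wildcard — to a log2 fold change; matching entries add up.
    """

    name: str
    size: int
    effects: Mapping[tuple[str | None, str | None, str | None], float]

    def log2_effect(self, strain: str, condition: str, phase: str) -> float:
        total = 0.0
        for (s, c, p), value in self.effects.items():
            if (s is None or s == strain) and (c is None or c == condition) and (
                p is None or p == phase
            ):
                total += value
        return total


def _phase_effects(condition: str, phases: Sequence[str], values: Sequence[float]):
    return {
        (None, condition, phase): val
        for phase, val in zip(phases, values)
        if val != 0.0
    }


def study_regulons() -> tuple[Regulon, ...]:
    """Default regulon set emulating the study's expression programs.

    Respiration proteins rise through the aerobic diauxic shift into
    stationary phase but stay flat anaerobically; ribosomal proteins fall
    toward stationary phase in both conditions; storage-carbohydrate and
    stress proteins rise upon glucose exhaustion; cell-periphery proteins
    rise anaerobically in stationary phase; the MG strain lacks a small set
    of deleted isoenzymes and slightly over-expresses a compensating one.
    """
    aero = ("ME", "LE", "ED", "MD", "MS")
    anae = ("ME", "LE", "ES", "MS")
    return (
        Regulon("respiration", 60, _phase_effects("aerobic", aero, (0, 0.6, 1.3, 1.8, 2.2))),
        Regulon(
            "ribosome",
            60,
            {
                **_phase_effects("aerobic", aero, (0, -0.3, -0.8, -1.2, -1.6)),
                **_phase_effects("anaerobic", anae, (0, -0.4, -0.9, -1.2)),
            },
        ),
        Regulon(
            "storage_carbohydrate",
            50,
            {
                **_phase_effects("aerobic", aero, (0, 0.4, 1.2, 1.4, 1.6)),
                **_phase_effects("anaerobic", anae, (0, 0.7, 1.3, 1.5)),
            },
        ),
        Regulon(
            "stress",
            40,
            {
                **_phase_effects("aerobic", aero, (0, 0, 0.5, 0.9, 1.4)),
                **_phase_effects("anaerobic", anae, (0, 0, 0.7, 1.3)),
            },
        ),
        Regulon(
            "cell_periphery",
            30,
            {
                **_phase_effects("aerobic", aero, (0, 0, 0.2, 0.3, 0.4)),
                **_phase_effects("anaerobic", anae, (0, 0, 0.3, 0.9)),
            },
        ),
        Regulon("mg_deletion", 15, {("MG", None, None): -5.0}),
        Regulon("mg_compensation", 5, {("MG", None, None): 0.5}),
    )


@dataclass
class SimConfig:
    """Full description of one simulated multi-plex experiment.

    Noise levels are stated as linear-scale RSD % (the reporting convention
    for experimental variation); all noise is multiplicative log-normal,
    since reporter intensities are positive and heteroscedastic on the
    linear scale.
    """

    n_proteins: int = 1000
    regulons: tuple[Regulon, ...] = field(default_factory=study_regulons)
    log10_abundance_mean: float = 2.0
    log10_abundance_sigma: float = 0.8
    bio_rsd: float = 15.0
    tech_rsd: float = 5.0
    plex_batch_rsd: float = 40.0
    plex_batch_factors: Mapping[str, float] | None = None
    channel_load_rsd: float = 2.0
    strains: tuple[str, ...] = ("CTRL", "MG")
    phases_by_condition: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "aerobic": ("ME", "LE", "ED", "MD", "MS"),
            "anaerobic": ("ME", "LE", "ES", "MS"),
        }
    )
    n_bio: int = 3
    n_tech: int = 2
    bridge_reference: tuple[str, str, str] = ("MG", "aerobic", "MS")
    bridge_channels: tuple[str, str] = ("126", "131")
    missing_mode: str = "mnar"  # "mnar" | "mcar" | "none"
    detect_mid_log10: float = 0.5
    detect_scale_log10: float = 0.35
    mcar_rate: float = 0.05
    peptide_count_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for value in (
            self.bio_rsd, self.tech_rsd, self.plex_batch_rsd, self.channel_load_rsd
        ):
            if value < 0:
                raise ValidationError("noise RSDs must be >= 0")
        sizes = sum(r.size for r in self.regulons)
        if sizes > self.n_proteins:
            raise ValidationError("regulons exceed the number of proteins")
        if self.missing_mode not in ("mnar", "mcar", "none"):
            raise ValidationError(f"unknown missing_mode {self.missing_mode!r}")

    def noise_free(self) -> "SimConfig":
        """Copy with every noise sigma set to zero and no missingness."""
        return replace(
            self,
            bio_rsd=0.0,
            tech_rsd=0.0,
            plex_batch_rsd=0.0,
            plex_batch_factors=None,
            channel_load_rsd=0.0,
            missing_mode="none",
            peptide_count_noise=False,
        )


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    baseline: pd.Series  # per protein
    log2_effects: pd.DataFrame  # columns (strain, condition, phase)
    regulon: pd.Series  # per protein regulon name ("" = none)
    sample_values: pd.DataFrame  # realized values before measurement noise
    genes: pd.Series  # accession -> gene symbol


@dataclass
class SimResult:
    plexes: list[PlexTable]
    design: ChannelDesign
    truth: SimTruth

    def gene_map(self) -> AccessionGeneMap:
        return AccessionGeneMap(genes=self.truth.genes.to_dict())


# ---------------------------------------------------------------------------
# plex layout
# ---------------------------------------------------------------------------

def _build_layout(config: SimConfig) -> list[tuple[str, list[tuple]]]:
    """Assign every sample (strain, condition, phase, bio, tech) to a plex.

    Anaerobic samples of one strain × biological replicate fill one plex
    exactly (4 phases × 2 tech = 8 sample channels + 2 bridges); aerobic
    samples are packed in order into plexes of up to 8 sample channels.
    """
    n_free = len(TMT10_CHANNELS) - len(config.bridge_channels)
    plexes: list[tuple[str, list[tuple]]] = []
    counter = 0

    def new_plex(samples: list[tuple]) -> None:
        nonlocal counter
        counter += 1
        plexes.append((f"plex{counter:02d}", samples))

    aerobic: list[tuple] = []
    for strain in config.strains:
        for bio in range(1, config.n_bio + 1):
            for condition, phases in config.phases_by_condition.items():
                samples = [
                    (strain, condition, phase, bio, tech)
                    for phase in phases
                    for tech in range(1, config.n_tech + 1)
                ]
                if condition == "aerobic":
                    aerobic.extend(samples)
                else:
                    for start in range(0, len(samples), n_free):
                        new_plex(samples[start: start + n_free])
    for start in range(0, len(aerobic), n_free):
        new_plex(aerobic[start: start + n_free])
    return plexes


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig) -> SimResult:
    """Generate plex tables, a channel design and the ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accessions = pd.Index([f"SP{i:04d}" for i in range(n)], name="accession")
    genes = pd.Series([f"GEN{i:04d}" for i in range(n)], index=accessions)

    baseline = pd.Series(
        10.0 ** rng.normal(config.log10_abundance_mean, config.log10_abundance_sigma, n),
        index=accessions,
        name="baseline",
    )

    # regulon membership: disjoint random subsets
    order = rng.permutation(n)
    regulon = pd.Series([""] * n, index=accessions, dtype=object)
    cursor = 0
    members: dict[str, np.ndarray] = {}
    for reg in config.regulons:
        idx = order[cursor: cursor + reg.size]
        cursor += reg.size
        members[reg.name] = idx
        regulon.iloc[idx] = reg.name

    groups = [
        (strain, condition, phase)
        for strain in config.strains
        for condition, phases in config.phases_by_condition.items()
        for phase in phases
    ]
    effects = pd.DataFrame(
        0.0,
        index=accessions,
        columns=pd.MultiIndex.from_tuples(groups, names=["strain", "condition", "phase"]),
    )
    for reg in config.regulons:
        idx = members[reg.name]
        for strain, condition, phase in groups:
            value = reg.log2_effect(strain, condition, phase)
            if value:
                effects.iloc[idx, effects.columns.get_loc((strain, condition, phase))] = value

    # realized per-sample values (biological effect, before measurement noise)
    sigma_bio = rsd_to_sigma_ln(config.bio_rsd)
    sample_cols = [
        (strain, condition, phase, bio)
        for strain, condition, phase in groups
        for bio in range(1, config.n_bio + 1)
    ]
    sample_values = pd.DataFrame(
        index=accessions,
        columns=pd.MultiIndex.from_tuples(
            sample_cols, names=["strain", "condition", "phase", "bio_replicate"]
        ),
        dtype=float,
    )
    for strain, condition, phase in groups:
        true = baseline.to_numpy() * 2.0 ** effects[(strain, condition, phase)].to_numpy()
        for bio in range(1, config.n_bio + 1):
            noise = rng.lognormal(0.0, sigma_bio, n) if sigma_bio > 0 else 1.0
            sample_values[(strain, condition, phase, bio)] = true * noise

    sample_values = sample_values.sort_index(axis=1)
    ref_strain, ref_condition, ref_phase = config.bridge_reference
    pool = sample_values[(ref_strain, ref_condition, ref_phase)].mean(axis=1)

    layout = _build_layout(config)
    sigma_batch = rsd_to_sigma_ln(config.plex_batch_rsd)
    sigma_load = rsd_to_sigma_ln(config.channel_load_rsd)
    sigma_tech = rsd_to_sigma_ln(config.tech_rsd)

    design_rows = []
    plexes: list[PlexTable] = []
    log10_baseline = np.log10(baseline.to_numpy())
    for plex_id, samples in layout:
        if config.plex_batch_factors is not None:
            batch = float(config.plex_batch_factors[plex_id])
        else:
            batch = float(rng.lognormal(0.0, sigma_batch)) if sigma_batch > 0 else 1.0

        free_channels = [c for c in TMT10_CHANNELS if c not in config.bridge_channels]
        channel_specs: list[tuple[str, tuple | None]] = [
            (config.bridge_channels[0], None)
        ]
        channel_specs += list(zip(free_channels, samples))
        channel_specs.append((config.bridge_channels[-1], None))

        data = pd.DataFrame(index=accessions)
        data["gene"] = genes
        data["description"] = [f"Synthetic protein {g}" for g in genes]
        lam = np.clip(3.0 * log10_baseline, 0.3, 40.0)
        if config.peptide_count_noise:
            n_unique = 1 + rng.poisson(lam)
            n_peptides = n_unique + rng.poisson(0.5 * lam)
        else:
            # deterministic identification in the noise-free limit
            n_unique = np.maximum(2, 1 + np.round(lam).astype(int))
            n_peptides = n_unique + np.round(0.5 * lam).astype(int)
        data["n_peptides"] = n_peptides
        data["n_unique_peptides"] = n_unique

        channel_labels = []
        base_columns = []
        bridge_tech = 0
        for channel, sample in channel_specs:
            load = float(rng.lognormal(0.0, sigma_load)) if sigma_load > 0 else 1.0
            tech_noise = (
                rng.lognormal(0.0, sigma_tech, n) if sigma_tech > 0 else 1.0
            )
            if sample is None:
                bridge_tech += 1
                base = pool.to_numpy()
                design_rows.append(
                    (plex_id, channel, ref_strain, ref_condition, ref_phase, 0,
                     bridge_tech, True)
                )
            else:
                strain, condition, phase, bio, tech = sample
                base = sample_values[(strain, condition, phase, bio)].to_numpy()
                design_rows.append(
                    (plex_id, channel, strain, condition, phase, bio, tech, False)
                )
            base_columns.append(base)
            data[channel] = base * batch * load * tech_noise
            channel_labels.append(channel)

        # plex-level missingness: detection depends only on the protein's
        # latent abundance in this plex, not on realized measurement noise
        if config.missing_mode == "mnar":
            latent = np.column_stack(base_columns).mean(axis=1)
            z = np.log10(latent) - config.detect_mid_log10
            p_detect = 1.0 / (1.0 + np.exp(-z / config.detect_scale_log10))
            detected = rng.random(n) < p_detect
        elif config.missing_mode == "mcar":
            detected = rng.random(n) >= config.mcar_rate
        else:
            detected = np.ones(n, dtype=bool)
        data = data.loc[detected].copy()

        plexes.append(
            PlexTable(plex_id, data, tuple(channel_labels)).validate()
        )

    design = ChannelDesign(pd.DataFrame(design_rows, columns=DESIGN_COLUMNS))
    truth = SimTruth(
        baseline=baseline,
        log2_effects=effects,
        regulon=regulon,
        sample_values=sample_values,
        genes=genes,
    )
    return SimResult(plexes=plexes, design=design, truth=truth)


# ---------------------------------------------------------------------------
# synthetic proteomes
# ---------------------------------------------------------------------------

def simulate_fasta(
    n_proteins: int,
    mean_length: float = 350.0,
    sd_length: float = 100.0,
    kr_frequency: float = 0.11,
    seed: int = 0,
) -> ProteomeDB:
    """Random protein sequences with controllable K/R frequency.

    Residues are drawn i.i.d. with P(K) = P(R) = ``kr_frequency``/2 and the
    remaining mass spread uniformly over the other 18 canonical residues, so
    tryptic fragment lengths are approximately geometric with mean
    1/``kr_frequency``.  Deterministic under ``seed``.
    """
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    if not 0.0 <= kr_frequency < 1.0:
        raise ValidationError("kr_frequency must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    residues = np.array(list(CANONICAL_20))
    probs = np.full(20, (1.0 - kr_frequency) / 18.0)
    for aa in "KR":
        probs[CANONICAL_20.index(aa)] = kr_frequency / 2.0
    records: dict[str, ProteinRecord] = {}
    for i in range(n_proteins):
        length = max(20, int(round(rng.normal(mean_length, sd_length))))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        accession = f"SYN{i:04d}"
        mono, avg = sequence_masses(seq)
        records[accession] = ProteinRecord(
            accession, f"{accession} synthetic protein", seq, mono, avg
        )
    return ProteomeDB(records)
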