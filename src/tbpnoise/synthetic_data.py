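"""Synthetic data generators emulating the analysis' input datasets.

Every downstream stage is exercised on data drawn here: promoter FASTA
with planted TBS motifs, co-activator occupancy tables, PBM probe
intensities, genome-wide mean/CV noise tables, TBP turnover values and
flow-cytometry event streams.  Each generator is a pure function of
``(config, master seed)`` — reruns are bit-identical — and ships a truth
table so planted labels can be checked exactly after classification.

The statistical structure mirrors the real data's reported features:

* SAGA (Spt20p) occupancy ordered T5 > A5 > TATA-like, TFIID (Taf1p)
  flat across TBS classes, Mot1p tracking the SAGA and TBP draws;
* PBM intensity ordered TATA-box > TATA-like > other and T5 > A5;
* CV inversely related to mean abundance (cv = k / sqrt(mean)) with
  class-dependent DM offsets on top;
* TBP turnover confined to the observed [0.008, 0.051] a.u. range with
  TATA-box promoters turning over faster than TATA-like;
* cytometry events whose GFP scales multiplicatively with cell size.

Noise is lognormal throughout: occupancies, intensities and abundances
are strictly positive and right-skewed, like the underlying assays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tbs_classify import CONSENSUS, IUPAC, count_mismatches

__all__ = [
    "GeneratorConfig",
    "gen_promoters",
    "gen_occupancy",
    "gen_pbm",
    "gen_noise_table",
    "gen_cytometry",
    "gen_turnover",
    "write_promoter_fasta",
]

CLASS_LABELS = ("TATA-box-T5", "TATA-box-A5", "TATA-like", "other")

# fixed stream tags so each generator draws from an independent,
# reproducible substream of the master seed
_STREAMS = {
    "promoters": 11,
    "occupancy": 12,
    "pbm": 13,
    "noise": 14,
    "cytometry": 15,
    "turnover": 16,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of every synthetic dataset; defaults define the study conditions."""

    seed: int = 0
    n_genes: int = 2000
    promoter_length: int = 120
    #: proportions over (TATA-box-T5, TATA-box-A5, TATA-like, other)
    class_mix: tuple[float, ...] = (0.10, 0.10, 0.30, 0.50)
    background_gc: float = 0.8

    # occupancy generator
    regulation_shift: float = 3.0  # fold change regulated vs not
    class_shift: float = 1.3  # fold change per class step (Spt20p, TBP)
    occupancy_sigma: float = 0.2  # lognormal sigma (natural log)
    missing_rate: float = 0.02
    #: probability a gene of each class is planted SAGA-regulated
    saga_rate_by_class: tuple[float, ...] = (0.85, 0.75, 0.55, 0.36)
    tfiid_rate: float = 0.5

    # PBM generator
    pbm_replicates: int = 8
    n_tatalike_motifs: int = 40
    n_other_motifs: int = 60
    #: median intensity (a.u.) per group: T5, A5, TATA-like, other
    pbm_means: tuple[float, ...] = (3000.0, 2200.0, 1200.0, 600.0)
    pbm_sigma: float = 0.25

    # noise-table generator
    mean_abundance: float = 1000.0  # a.u., lognormal median
    mean_log_sigma: float = 1.0  # natural-log sigma of abundance
    cv_scale: float = 9.5  # k in cv = k / sqrt(mean)
    #: DM offsets (log10 units) per class: T5, A5, TATA-like, other
    dm_offsets: tuple[float, ...] = (0.15, 0.10, 0.0, -0.05)
    dm_residual_sigma: float = 0.05  # log10 units

    # turnover generator (a.u.; observed range [0.008, 0.051])
    turnover_tata: tuple[float, float] = (0.020, 0.051)
    turnover_talike: tuple[float, float] = (0.008, 0.035)
    turnover_other: tuple[float, float] = (0.008, 0.040)

    # cytometry generator
    n_events: int = 20000
    n_replicates: int = 2
    true_cv: float = 0.3
    size_sigma: float = 0.25  # lognormal sigma of cell size
    size_confound: float = 1.0  # exponent of size in raw GFP
    channel_sigma: float = 0.05  # scatter channel noise (log)
    fsc_scale: float = 60000.0
    ssc_scale: float = 25000.0
    gfp_scale: float = 1000.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if min(self.class_mix) < 0:
            raise ValueError("class_mix proportions must be >= 0")
        for name in ("n_genes", "n_events", "pbm_replicates", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "occupancy_sigma",
            "pbm_sigma",
            "dm_residual_sigma",
            "size_sigma",
            "channel_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


def _consensus_instance(rng: np.random.Generator, pos5: str | None = None) -> str:
    """A uniformly drawn exact match to the TATA consensus."""
    bases = []
    for i, code in enumerate(CONSENSUS):
        allowed = sorted(IUPAC[code])
        if i == 4 and pos5 is not None:
            bases.append(pos5)
        else:
            bases.append(allowed[rng.integers(len(allowed))])
    return "".join(bases)


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Introduce exactly ``n_mut`` consensus-violating substitutions."""
    seq_list = list(seq)
    positions = rng.choice(len(seq_list), size=n_mut, replace=False)
    for pos in positions:
        disallowed = sorted(set("ACGT") - IUPAC[CONSENSUS[pos]])
        seq_list[pos] = disallowed[rng.integers(len(disallowed))]
    return "".join(seq_list)


def _random_other(rng: np.random.Generator, gc: float = 0.5) -> str:
    """A random 8-mer at least 3 mismatches from the consensus."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while True:
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=8, p=probs)])
        if count_mismatches(seq) >= 3:
            return seq


def _background(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _planted_is_unique_best(
    seq: str, offset: int, planted_mm: int, floor: int | None = None
) -> bool:
    """True when every non-planted window scores worse than the planted one.

    ``floor`` additionally requires all non-planted windows to carry at
    least that many mismatches (used for "other" genes, where the
    planted 8-mer itself is >= 3 mismatches and nothing may look like a
    TATA site).  Windows overlapping a periodic planted motif inherit
    part of its sequence, so strict dominance — not a global mismatch
    floor — is the feasible cleanliness guarantee.
    """
    for off in range(len(seq) - 7):
        if off == offset:
            continue
        mm = count_mismatches(seq[off : off + 8])
        if mm <= planted_mm or (floor is not None and mm < floor):
            return False
    return True


def gen_promoters(config: GeneratorConfig) -> pd.DataFrame:
    """Promoter sequences with one planted TBS of an assigned class.

    Returns one row per gene: ``gene_id``, ``tbs_class``, ``subset``,
    ``offset`` (0-based planted position), ``planted_seq`` and the full
    promoter ``sequence``.  The GC-rich background is rejection-sampled
    so every non-planted window carries at least 3 mismatches, making
    the planted site the unique best match for TATA-box and TATA-like
    genes.
    """
    rng = _rng(config, "promoters")
    n = config.n_genes
    classes = rng.choice(4, size=n, p=np.asarray(config.class_mix))
    rows = []
    for g in range(n):
        label = CLASS_LABELS[classes[g]]
        def _draw_planted() -> tuple[str, str, str]:
            if label == "TATA-box-T5":
                return _consensus_instance(rng, pos5="T"), "TATA-box", "T5"
            if label == "TATA-box-A5":
                return _consensus_instance(rng, pos5="A"), "TATA-box", "A5"
            if label == "TATA-like":
                seq = _mutate(
                    _consensus_instance(rng), int(rng.integers(1, 3)), rng
                )
                return seq, "TATA-like", "none"
            return _random_other(rng, gc=config.background_gc), "other", "none"

        planted, tbs_class, subset = _draw_planted()
        for attempt in range(200):  # rejection-sample a clean background
            if attempt and attempt % 20 == 0 and tbs_class != "other":
                # a periodic variant can make its own shifted windows
                # unbeatable; redraw the planted instance
                planted, tbs_class, subset = _draw_planted()
            offset = int(rng.integers(0, config.promoter_length - 8 + 1))
            bg = _background(rng, config.promoter_length, config.background_gc)
            seq = bg[:offset] + planted + bg[offset + 8 :]
            planted_mm = count_mismatches(planted)
            floor = 3 if tbs_class == "other" else None
            if tbs_class == "other":
                planted_mm = 2  # only the >= 3 floor applies
            if _planted_is_unique_best(seq, offset, planted_mm, floor=floor):
                break
        else:  # pragma: no cover - rejection succeeds within a few draws
            raise RuntimeError("could not sample a clean promoter background")
        rows.append(
            {
                "gene_id": f"gene{g:05d}",
                "tbs_class": tbs_class,
                "subset": subset,
                "offset": offset,
                "planted_seq": planted,
                "sequence": seq,
            }
        )
    columns = ["gene_id", "tbs_class", "subset", "offset", "planted_seq", "sequence"]
    return pd.DataFrame(rows, columns=columns)


def write_promoter_fasta(truth: pd.DataFrame, path: str | Path) -> None:
    """Write generated promoters as FASTA (ids = gene ids)."""
    records = [
        SeqRecord(Seq(row.sequence), id=row.gene_id, description="")
        for row in truth.itertuples()
    ]
    SeqIO.write(records, str(path), "fasta")


def _class_rank(truth: pd.DataFrame) -> np.ndarray:
    """Map each gene to its class index in CLASS_LABELS order."""
    key = truth["tbs_class"].astype(str) + ":" + truth["subset"].astype(str)
    mapping = {
        "TATA-box:T5": 0,
        "TATA-box:A5": 1,
        "TATA-like:none": 2,
        "other:none": 3,
    }
    return key.map(mapping).to_numpy()


def gen_occupancy(
    config: GeneratorConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lognormal ChIP occupancy table for TBP, Mot1p, Taf1p and Spt20p.

    Each gene is planted TFIID-regulated with probability
    ``tfiid_rate`` (independent of TBS class: TFIID occupancy is flat
    across classes) and SAGA-regulated with a class-dependent
    probability (highest for T5), so that Spt20p medians come out
    ordered T5 > A5 > TATA-like > other.  Mot1p occupancy is built from
    the gene's Spt20p and TBP draws (plus noise), tracking both.

    Returns ``(occupancy table, regulation truth)``; the truth carries
    the planted ``tfiid_regulated``/``saga_regulated`` flags and the
    derived ``coactivator_class``.
    """
    rng = _rng(config, "occupancy")
    n = len(truth)
    rank = _class_rank(truth)
    log_reg = np.log(config.regulation_shift) / 2.0
    log_cls = np.log(config.class_shift)
    # class offsets (log space): ordered effect for Spt20p and TBP, flat Taf1p
    cls_offset = np.array([1.0, 0.5, 0.0, -0.25])[rank] * log_cls

    saga_rate = np.asarray(config.saga_rate_by_class)[rank]
    saga_reg = rng.random(n) < saga_rate
    tfiid_reg = rng.random(n) < config.tfiid_rate

    noise = rng.normal(0.0, config.occupancy_sigma, size=(4, n))
    log_taf1 = np.where(tfiid_reg, log_reg, -log_reg) + noise[0]
    log_spt20 = np.where(saga_reg, log_reg, -log_reg) + cls_offset + noise[1]
    log_tbp = cls_offset + noise[2]
    log_mot1 = 0.5 * log_spt20 + 0.5 * log_tbp + noise[3]

    table = pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "TBP": np.exp(log_tbp),
            "Mot1p": np.exp(log_mot1),
            "Taf1p": np.exp(log_taf1),
            "Spt20p": np.exp(log_spt20),
        }
    )
    if config.missing_rate > 0:
        for col in ("TBP", "Mot1p", "Taf1p", "Spt20p"):
            mask = rng.random(n) < config.missing_rate
            table.loc[mask, col] = np.nan
    reg_truth = pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "tfiid_regulated": tfiid_reg,
            "saga_regulated": saga_reg,
            "coactivator_class": [
                f"{'+' if t else '-'}/{'+' if s else '-'}"
                for t, s in zip(tfiid_reg, saga_reg)
            ],
        }
    )
    return table, reg_truth


def gen_pbm(config: GeneratorConfig) -> pd.DataFrame:
    """PBM probe table with class-ordered intensities.

    All 8 exact consensus instances (4 per T5/A5 subset) are included,
    plus ``n_tatalike_motifs`` distinct 1-2 mismatch variants and
    ``n_other_motifs`` random 8-mers with >= 3 mismatches.  Every motif
    is measured on ``pbm_replicates`` probes with lognormal noise around
    its class median.
    """
    rng = _rng(config, "pbm")
    t5_mean, a5_mean, talike_mean, other_mean = config.pbm_means
    motifs: list[tuple[str, float]] = []
    for pos5, mean in (("T", t5_mean), ("A", a5_mean)):
        for w7 in "AT":
            for r8 in "AG":
                motifs.append(("TATA" + pos5 + "A" + w7 + r8, mean))
    seen = {m for m, _ in motifs}
    while len(seen) < 8 + config.n_tatalike_motifs:
        seq = _mutate(_consensus_instance(rng), int(rng.integers(1, 3)), rng)
        if seq not in seen:
            seen.add(seq)
            motifs.append((seq, talike_mean))
    while len(seen) < 8 + config.n_tatalike_motifs + config.n_other_motifs:
        seq = _random_other(rng)
        if seq not in seen:
            seen.add(seq)
            motifs.append((seq, other_mean))
    rows = []
    probe_no = 0
    for motif, mean in motifs:
        draws = mean * np.exp(
            rng.normal(0.0, config.pbm_sigma, size=config.pbm_replicates)
        )
        for value in draws:
            rows.append(
                {
                    "probe_id": f"probe{probe_no:06d}",
                    "motif": motif,
                    "intensity": float(value),
                }
            )
            probe_no += 1
    return pd.DataFrame(rows, columns=["probe_id", "motif", "intensity"])


def gen_noise_table(
    config: GeneratorConfig, truth: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene mean abundance and CV with an inverse mean-CV trend.

    ``cv = cv_scale / sqrt(mean) * 10**(class offset + residual)``: the
    baseline is exactly abundance-dependent, class DM offsets sit on top
    in log10 units (ordered T5 > A5 > TATA-like > other), and
    ``dm_residual_sigma`` adds gene-level scatter.  With zero offsets and
    zero residual the DM of every gene is identically zero.
    """
    rng = _rng(config, "noise")
    n = len(truth)
    rank = _class_rank(truth)
    mean = config.mean_abundance * np.exp(
        rng.normal(0.0, config.mean_log_sigma, size=n)
    )
    offsets = np.asarray(config.dm_offsets)[rank]
    residual = rng.normal(0.0, config.dm_residual_sigma, size=n)
    cv = config.cv_scale / np.sqrt(mean) * 10.0 ** (offsets + residual)
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "tbs_class": truth["tbs_class"].to_numpy(),
            "subset": truth["subset"].to_numpy(),
            "mean": mean,
            "cv": cv,
        }
    )


def gen_turnover(config: GeneratorConfig, truth: pd.DataFrame) -> pd.Series:
    """TBP turnover values (a.u.) per gene, uniform within class ranges.

    TATA-box promoters draw from the upper part of the observed
    [0.008, 0.051] range and TATA-like from the lower, giving the
    faster turnover of TATA-box promoters.
    """
    rng = _rng(config, "turnover")
    ranges = {
        "TATA-box": config.turnover_tata,
        "TATA-like": config.turnover_talike,
        "other": config.turnover_other,
    }
    values = np.empty(len(truth))
    for i, cls in enumerate(truth["tbs_class"]):
        lo, hi = ranges[cls]
        values[i] = rng.uniform(lo, hi)
    return pd.Series(values, index=truth["gene_id"].to_numpy(), name="turnover")


def gen_cytometry(
    config: GeneratorConfig, true_cv: float | None = None
) -> pd.DataFrame:
    """Flow-cytometry events with a multiplicative size confound.

    Per event a cell size ``s`` is drawn lognormal; FSC-A and SSC-A are
    monotone in ``s`` with lognormal channel noise, clipped into the
    open 18-bit ADC range; expression ``g`` is lognormal with CV
    ``true_cv``; and ``gfp = gfp_scale * s**size_confound * g``.  With
    ``size_confound = 0`` the raw GFP CV already equals ``true_cv``.
    Events are split evenly over ``n_replicates`` replicates.
    """
    rng = _rng(config, "cytometry")
    if true_cv is None:
        true_cv = config.true_cv
    n = config.n_events * config.n_replicates
    size = np.exp(rng.normal(0.0, config.size_sigma, size=n))
    sigma_g = np.sqrt(np.log1p(true_cv**2))
    # mean-one lognormal expression with the requested CV
    g = np.exp(rng.normal(-0.5 * sigma_g**2, sigma_g, size=n))
    fsc = config.fsc_scale * size * np.exp(
        rng.normal(0.0, config.channel_sigma, size=n)
    )
    ssc = config.ssc_scale * size * np.exp(
        rng.normal(0.0, config.channel_sigma, size=n)
    )
    ceiling = 2**18 - 1
    fsc = np.clip(fsc, 1e-6, ceiling - 1e-6)
    ssc = np.clip(ssc, 1e-6, ceiling - 1e-6)
    gfp = config.gfp_scale * size**config.size_confound * g
    return pd.DataFrame(
        {
            "fsc_a": fsc,
            "ssc_a": ssc,
            "gfp": gfp,
            "sample": "synthetic",
            "replicate": np.repeat(
                np.arange(1, config.n_replicates + 1), config.n_events
            ),
        }
    )
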