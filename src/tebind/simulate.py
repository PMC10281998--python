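"""Seeded simulator of a toy genome with planted regulatory signal.

Generates, from one integer seed, every input the analysis stages consume:

* a random two-chromosome genome with several TE subfamilies, each copy a
  jittered-length rendition of a random subfamily consensus, placed without
  overlap on a random strand;
* a 9-bp motif (default CCTTTAATC) substituted into a configurable fraction
  of the copies of designated subfamilies, reverse-complemented on minus
  strands;
* ChIP-seq-like peaks: fixed-width intervals whose summit sits on a planted
  motif midpoint, plus uniformly placed background peaks;
* genes, a configurable fraction of which have their TSS planted close to a
  peak summit;
* a 6-time-point replicate TPM matrix in which each "cluster" gene has its
  mean expression raised by a multiplicative effect at one time point, with
  lognormal noise.

Truth tables record every planted label so recovery is assertable. All draws
run through one integer-seeded numpy Generator in a fixed order, so a given
config is byte-reproducible across platforms.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    GeneRecord,
    GenomicInterval,
    PeakRecord,
    TECopy,
    reverse_complement,
    write_bed,
    write_consensus_table,
    write_fasta,
    write_gtf_genes,
)

__all__ = ["SubfamilySpec", "SimConfig", "SimulatedData", "simulate_dataset",
           "simulate_genome", "simulate_peaks", "simulate_genes",
           "simulate_expression", "write_dataset"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
DEFAULT_MOTIF = "CCTTTAATC"


@dataclass(frozen=True)
class SubfamilySpec:
    """One simulated TE subfamily."""

    name: str
    family: str
    te_class: str
    consensus_length: int
    n_copies: int
    jitter: float = 0.10  # copy length = consensus * (1 + U(-jitter, jitter))
    planting_rate: float = 0.0  # fraction of copies carrying the motif
    divergence: float = 0.15  # per-base substitution rate per copy

    def __post_init__(self) -> None:
        if not 0 <= self.planting_rate <= 1:
            raise ValueError(f"{self.name}: planting_rate must be in [0,1]")
        if self.n_copies < 0 or self.consensus_length <= 0:
            raise ValueError(f"{self.name}: bad copy count or consensus length")


def _default_subfamilies() -> tuple[SubfamilySpec, ...]:
    # A toy cast mirroring the study's players: the MERVL LTR (MT2_Mm) and
    # the B1 SINE subfamilies carry the shared motif; the rest are background.
    return (
        SubfamilySpec("MT2_Mm", "ERVL", "LTR", 500, 60, 0.10, 0.9),
        SubfamilySpec("B1_Mm", "Alu", "SINE", 150, 150, 0.10, 0.9),
        SubfamilySpec("B1_Mus1", "Alu", "SINE", 150, 120, 0.10, 0.0),
        SubfamilySpec("B1_Mus2", "Alu", "SINE", 150, 120, 0.10, 0.0),
        SubfamilySpec("RLTR17", "ERVK", "LTR", 400, 80, 0.10, 0.0),
        SubfamilySpec("MTA_Mm", "ERVL-MaLR", "LTR", 350, 100, 0.10, 0.0),
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    subfamilies: tuple[SubfamilySpec, ...] = field(
        default_factory=_default_subfamilies
    )
    motif: str = DEFAULT_MOTIF
    peak_width: int = 300
    motif_peak_fraction: float = 1.0  # fraction of planted instances peaked
    n_background_peaks: int = 12
    n_genes: int = 300
    near_gene_fraction: float = 0.3  # genes with TSS planted near a summit
    near_gene_max_dist: int = 500
    gene_length: int = 1_000
    timepoints: tuple[int, ...] = (0, 12, 24, 36, 48, 72)
    n_replicates: int = 2
    cluster_fraction: float = 0.5  # genes given a peaked temporal profile
    effect_size: float = 4.0  # fold elevation at the cluster time point
    base_tpm_log_mean: float = np.log(10.0)
    base_tpm_log_sigma: float = 1.0
    noise_sigma: float = 0.25  # lognormal replicate noise, 0 = noiseless
    max_placement_attempts: int = 10_000


@dataclass(frozen=True)
class MotifInstance:
    """Genomic location of one planted motif occurrence."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    copy_id: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SimulatedData:
    config: SimConfig
    genome: dict[str, str]
    te_copies: list[TECopy]
    consensus_table: dict[str, int]
    motif_instances: list[MotifInstance]
    peaks: list[PeakRecord]
    genes: list[GeneRecord]
    gene_peak_distance: dict[str, int | None]  # planted TSS-summit distance
    tpm: pd.DataFrame
    true_clusters: dict[str, int | None]

    @property
    def deg_ids(self) -> list[str]:
        """Genes planted with a temporal cluster (the simulated DEG list)."""
        return [g for g, c in self.true_clusters.items() if c is not None]


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _pick_chrom(rng: np.random.Generator, chrom_sizes: dict[str, int]) -> str:
    names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in names], dtype=float)
    return names[rng.choice(len(names), p=sizes / sizes.sum())]


class _Occupancy:
    """Disjoint placed intervals per chromosome, for rejection sampling."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def clashes(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom, [])
        ends = self._ends.get(chrom, [])
        i = bisect.bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_right(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[TECopy], dict[str, int], list[MotifInstance]]:
    """Random genome + placed TE copies + consensus table + motif truth."""
    rng = _rng(config, 1)
    arrays = {
        chrom: _random_seq(rng, size) for chrom, size in config.chrom_sizes.items()
    }
    consensus_seqs = {
        spec.name: _random_seq(rng, spec.consensus_length).tobytes().decode()
        for spec in config.subfamilies
    }
    motif = config.motif.upper()
    occupancy = _Occupancy()
    copies: list[TECopy] = []
    instances: list[MotifInstance] = []

    for spec in config.subfamilies:
        consensus = consensus_seqs[spec.name]
        for i in range(spec.n_copies):
            jitter = rng.uniform(-spec.jitter, spec.jitter)
            length = max(len(motif), round(spec.consensus_length * (1.0 + jitter)))
            # rejection-sample a non-overlapping placement
            for attempt in range(config.max_placement_attempts):
                chrom = _pick_chrom(rng, config.chrom_sizes)
                limit = config.chrom_sizes[chrom] - length
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit + 1))
                if not occupancy.clashes(chrom, start, start + length):
                    break
            else:
                raise RuntimeError(
                    f"could not place copy {spec.name}.{i} without overlap in "
                    f"{config.max_placement_attempts} attempts; reduce copy "
                    "counts or enlarge the genome"
                )
            occupancy.add(chrom, start, start + length)
            strand = "+" if rng.random() < 0.5 else "-"

            seq = consensus[:length]
            if length > len(consensus):
                seq += _random_seq(rng, length - len(consensus)).tobytes().decode()
            if spec.divergence > 0:
                # neutral per-copy divergence from the consensus; the planted
                # motif below stays intact, emulating a conserved bound site
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                hit = rng.random(length) < spec.divergence
                arr[hit] = _random_seq(rng, int(hit.sum()))
                seq = arr.tobytes().decode()

            copy_id = f"{spec.name}.{i}"
            planted = rng.random() < spec.planting_rate
            if planted:
                offset = int(rng.integers(0, length - len(motif) + 1))
                seq = seq[:offset] + motif + seq[offset + len(motif):]

            genomic = seq if strand == "+" else reverse_complement(seq)
            arrays[chrom][start : start + length] = np.frombuffer(
                genomic.encode(), dtype="S1"
            )
            copies.append(
                TECopy(
                    GenomicInterval(chrom, start, start + length, strand),
                    spec.name,
                    spec.family,
                    spec.te_class,
                    copy_id,
                    spec.consensus_length,
                )
            )
            if planted:
                if strand == "+":
                    m_start = start + offset
                else:
                    m_start = start + length - offset - len(motif)
                instances.append(
                    MotifInstance(
                        chrom, m_start, m_start + len(motif), strand,
                        spec.name, copy_id,
                    )
                )

    genome = {c: a.tobytes().decode() for c, a in arrays.items()}
    consensus_table = {s.name: s.consensus_length for s in config.subfamilies}
    return genome, copies, consensus_table, instances


def simulate_peaks(
    config: SimConfig, motif_instances: Sequence[MotifInstance]
) -> list[PeakRecord]:
    """Motif-anchored peaks (summit = motif midpoint) plus background peaks."""
    rng = _rng(config, 2)
    w = config.peak_width
    peaks: list[PeakRecord] = []

    n_anchored = round(config.motif_peak_fraction * len(motif_instances))
    idx = (
        sorted(rng.choice(len(motif_instances), size=n_anchored, replace=False))
        if n_anchored < len(motif_instances)
        else range(len(motif_instances))
    )
    for i in idx:
        inst = motif_instances[i]
        size = config.chrom_sizes[inst.chrom]
        start = max(0, min(inst.midpoint - w // 2, size - w))
        peaks.append(
            PeakRecord(
                GenomicInterval(inst.chrom, start, start + w),
                summit=inst.midpoint,
                peak_id=f"peak_m{len(peaks)}",
            )
        )
    for _ in range(config.n_background_peaks):
        chrom = _pick_chrom(rng, config.chrom_sizes)
        start = int(rng.integers(0, config.chrom_sizes[chrom] - w + 1))
        peaks.append(
            PeakRecord(
                GenomicInterval(chrom, start, start + w),
                summit=start + w // 2,
                peak_id=f"peak_b{len(peaks)}",
            )
        )
    return peaks


def simulate_genes(
    config: SimConfig, peaks: Sequence[PeakRecord]
) -> tuple[list[GeneRecord], dict[str, int | None]]:
    """Genes with TSSs either planted near peak summits or placed uniformly.

    Returns the genes and a truth map gene_id -> planted TSS-summit distance
    (None for uniformly placed genes).
    """
    rng = _rng(config, 3)
    genes: list[GeneRecord] = []
    truth: dict[str, int | None] = {}
    glen = config.gene_length
    n_near = round(config.near_gene_fraction * config.n_genes)
    for i in range(config.n_genes):
        gid = f"gene{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if i < n_near and peaks:
            peak = peaks[int(rng.integers(0, len(peaks)))]
            dist = int(rng.integers(0, config.near_gene_max_dist + 1))
            sign = 1 if rng.random() < 0.5 else -1
            tss = peak.summit + sign * dist
            chrom = peak.interval.chrom
            truth[gid] = dist
        else:
            chrom = _pick_chrom(rng, config.chrom_sizes)
            tss = int(rng.integers(0, config.chrom_sizes[chrom]))
            truth[gid] = None
        size = config.chrom_sizes[chrom]
        tss = max(glen, min(tss, size - glen - 1))  # keep the body in bounds
        if strand == "+":
            iv = GenomicInterval(chrom, tss, tss + glen, "+")
        else:
            iv = GenomicInterval(chrom, tss - glen + 1, tss + 1, "-")
        genes.append(GeneRecord(gid, gid.upper(), iv))
    return genes, truth


def simulate_expression(
    config: SimConfig, gene_ids: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, int | None]]:
    """Replicate TPM matrix over the time course plus true cluster labels.

    Cluster genes have their mean multiplied by ``effect_size`` at their
    time point; every replicate value then gets lognormal noise
    exp(N(0, noise_sigma)). noise_sigma = 0 gives the exact means.
    """
    rng = _rng(config, 4)
    T, R = len(config.timepoints), config.n_replicates
    truth: dict[str, int | None] = {}
    rows = np.empty((len(gene_ids), T * R))
    for gi, gid in enumerate(gene_ids):
        base = float(
            rng.lognormal(config.base_tpm_log_mean, config.base_tpm_log_sigma)
        )
        if rng.random() < config.cluster_fraction:
            ti = int(rng.integers(0, T))
            truth[gid] = int(config.timepoints[ti])
        else:
            ti = -1
            truth[gid] = None
        means = np.full(T, base)
        if ti >= 0:
            means[ti] *= config.effect_size
        noise = (
            rng.lognormal(0.0, config.noise_sigma, size=(T, R))
            if config.noise_sigma > 0
            else np.ones((T, R))
        )
        rows[gi] = (means[:, None] * noise).ravel()
    columns = [
        f"t{tp}_r{r + 1}" for tp in config.timepoints for r in range(R)
    ]
    return pd.DataFrame(rows, index=list(gene_ids), columns=columns), truth


def timepoint_means(tpm: pd.DataFrame, timepoints: Sequence[int]) -> pd.DataFrame:
    """Collapse replicate columns t<tp>_r<i> to one mean column per time point."""
    out = {}
    for tp in timepoints:
        cols = [c for c in tpm.columns if c.startswith(f"t{tp}_r")]
        if not cols:
            raise KeyError(f"no replicate columns for time point {tp}")
        out[f"t{tp}"] = tpm[cols].mean(axis=1)
    return pd.DataFrame(out, index=tpm.index)


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Run every stage of the simulator under one seed."""
    genome, copies, consensus_table, instances = simulate_genome(config)
    peaks = simulate_peaks(config, instances)
    genes, gene_truth = simulate_genes(config, peaks)
    tpm, cluster_truth = simulate_expression(config, [g.gene_id for g in genes])
    return SimulatedData(
        config=config,
        genome=genome,
        te_copies=copies,
        consensus_table=consensus_table,
        motif_instances=instances,
        peaks=peaks,
        genes=genes,
        gene_peak_distance=gene_truth,
        tpm=tpm,
        true_clusters=cluster_truth,
    )


def write_dataset(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated artifact as plain text under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "te_bed": outdir / "te_copies.bed",
        "consensus": outdir / "consensus_lengths.tsv",
        "peaks": outdir / "peaks.narrowPeak",
        "genes": outdir / "genes.gtf",
        "tpm": outdir / "tpm.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(data.genome, paths["genome"])
    write_bed(data.te_copies, paths["te_bed"])
    write_consensus_table(data.consensus_table, paths["consensus"])
    write_bed(data.peaks, paths["peaks"])
    write_gtf_genes(
        [(g.gene_id, g.gene_name, g.interval) for g in data.genes], paths["genes"]
    )
    data.tpm.to_csv(paths["tpm"], sep="\t", index_label="gene_id", lineterminator="\n")
    truth = {
        "motif": data.config.motif,
        "motif_instances": [asdict(m) for m in data.motif_instances],
        "gene_peak_distance": data.gene_peak_distance,
        "true_clusters": data.true_clusters,
    }
    with open(paths["truth"], "w", newline="\n") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
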