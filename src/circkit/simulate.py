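"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of real-world input the toolkit consumes
— circRNA catalog dumps, a pan-cancer junction-count release with a matched
host-gene FPKM matrix, a toy genomic locus with exon/intron structure, qPCR
Ct tables produced from true copy numbers under a stated amplification
efficiency and Gaussian Ct noise, patient cohorts whose assay calls derive
from a latent High/Low status with a per-assay flip probability, and
longitudinal plasma series with a programmed resistance-emergence event.
Alongside every dataset a truth record is produced, sufficient to score the
downstream analysis without re-deriving parameters.

All generators are seed-deterministic: one global seed drives fixed
per-generator child streams (``default_rng([seed, generator_tag])``), so
regenerating any one dataset does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import METHODS

__all__ = [
    "SimConfig",
    "gen_catalog",
    "gen_pan_cancer",
    "gen_gene_model",
    "gen_qpcr",
    "gen_standard_series",
    "gen_cohort",
    "gen_longitudinal",
]

# fixed child-stream tags so generators are independently reproducible
_TAGS = {"catalog": 1, "pan_cancer": 2, "gene_model": 3, "qpcr": 4,
         "cohort": 5, "longitudinal": 6}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the conditions the analyses assume: a compendium-scale
    correlation screen at 250 samples, negative-binomial junction counts
    (mean 10, size 2: overdispersed like real capture data), lognormal
    FPKM, Ct noise of 0.15 cycles at efficiency 1.0, a 5% per-assay flip
    probability on cohort calls, and an order-of-magnitude plasma jump at
    the programmed emergence timepoint.
    """

    seed: int = 0
    # sizes
    n_samples: int = 250
    n_circ: int = 30
    n_genes: int = 30
    n_patients: int = 60
    n_timepoints: int = 10
    # catalog
    n_sources: int = 3
    n_species: int = 5
    source_coverage: float = 0.6  # P(a non-dominant circ appears in a given source)
    # pan-cancer counts
    nb_mean: float = 10.0
    nb_size: float = 2.0
    nb_mean_spiked: float = 50.0  # spiked candidates are top-quartile abundant
    fpkm_meanlog: float = 2.0
    fpkm_sdlog: float = 1.0
    spiked_rho: dict = field(default_factory=lambda: {"circ_0000": 0.8})
    # locus
    n_exons: int = 3
    exon_lengths: tuple = (120, 300, 90)
    intron_lengths: tuple = (800, 650)
    gc_content: float = 0.45
    locus_strand: str = "+"
    # qPCR
    efficiency: float = 1.0
    sigma_ct: float = 0.15
    ct_intercept: float = 40.0  # Ct of a single copy
    n_replicates: int = 3
    standard_decades: tuple = (11, 10, 9, 8, 7)  # 10^11 .. 10^7 copies
    # cohort
    flip_prob: float = 0.05
    missing_rate: float = 0.10
    prevalence: float = 0.5
    plasma_meanlog_high: float = np.log(800.0)
    plasma_meanlog_low: float = np.log(60.0)
    plasma_sdlog: float = 0.6
    # longitudinal
    emergence_time: int = 5
    emergence_fold: float = 10.0
    baseline_level: float = 20.0  # copies/ml floor before emergence
    noise_cv: float = 0.20

    def rng(self, generator: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _TAGS[generator]])


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# catalogs


def gen_catalog(cfg: SimConfig, outdir: str | Path | None = None):
    """Multi-source circRNA catalogs with one spiked dominant candidate.

    circ_0000 is present in every source, carries the highest total reads
    and junction ratio, and is conserved across all species; the rest appear
    in a random subset of sources with lower abundance and patchier
    conservation. Returns (catalogs, truth): ``catalogs`` is a list of
    (source_db, records) consumable by ``integrate_catalogs``; files are
    written in two dialects (BED-like 0-based; headered TSV 1-based
    inclusive) when ``outdir`` is given.
    """
    from .catalog import CircRecord

    rng = cfg.rng("catalog")
    sources = [f"db{chr(ord('A') + i)}" for i in range(cfg.n_sources)]
    species = ["human", "mouse", "rat", "macaque", "zebrafish"][: cfg.n_species]

    n = cfg.n_circ
    starts = np.sort(rng.choice(np.arange(1_000, 900_000, 50), size=n, replace=False))
    lengths = rng.integers(200, 2_000, size=n)
    dominant = "circ_0000"

    # per-circ intrinsic properties
    bsj = rng.integers(5, 60, size=n)
    total = bsj + rng.integers(5, 120, size=n)
    bsj[0] = 900          # spiked candidate: abundant and mostly circular
    total[0] = 1000
    if cfg.source_coverage <= 0:
        # disjoint sources: each circRNA annotated by exactly one database
        member = np.zeros((n, len(sources)), dtype=bool)
        for i in range(n):
            member[i, i % len(sources)] = True
    else:
        member = rng.random((n, len(sources))) < cfg.source_coverage
        member[:, 0] = True   # every circRNA exists somewhere
        member[0, :] = True   # the dominant candidate is in every source
    conserved = rng.random((n, len(species))) < 0.4
    conserved[:, 0] = True  # all are human records
    conserved[0, :] = True

    catalogs = []
    for j, src in enumerate(sources):
        records = []
        for i in range(n):
            if not member[i, j]:
                continue
            sp_list = [sp for k, sp in enumerate(species) if conserved[i, k]] \
                if j == 0 else ["human"]
            for sp in sp_list:
                records.append(
                    CircRecord(
                        circ_id=f"circ_{i:04d}",
                        chrom="chr7",
                        start=int(starts[i]),
                        end=int(starts[i] + lengths[i]),
                        strand="+",
                        host_gene="GENE0" if i == 0 else f"GENE{i}",
                        species=sp,
                        spliced_length=int(lengths[i]),
                        bsj_reads=int(bsj[i]),
                        total_junction_reads=int(total[i]),
                        source_db=src,
                    )
                )
        catalogs.append((src, records))

    truth = {
        "dominant": dominant,
        "membership": {f"circ_{i:04d}": [s for j, s in enumerate(sources) if member[i, j]]
                       for i in range(n)},
        "conservation": {f"circ_{i:04d}": [sp for k, sp in enumerate(species)
                                           if conserved[i, k]] for i in range(n)},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        # dialect 1: BED-like, 0-based half-open
        src, records = catalogs[0]
        with open(outdir / f"{src}.bed", "w") as fh:
            for r in records:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t0\t{r.strand}"
                         f"\t{r.bsj_reads}\t{r.total_junction_reads}\n")
        # remaining dialects: headered TSV, 1-based inclusive
        for src, records in catalogs[1:]:
            rows = [{"circ_id": r.circ_id, "chrom": r.chrom, "start": r.start + 1,
                     "end": r.end, "strand": r.strand, "host_gene": r.host_gene,
                     "species": r.species, "spliced_length": r.spliced_length,
                     "bsj_reads": r.bsj_reads,
                     "total_junction_reads": r.total_junction_reads}
                    for r in records]
            pd.DataFrame(rows).to_csv(outdir / f"{src}.tsv", sep="\t", index=False)
        with open(outdir / "catalog_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return catalogs, truth


# ---------------------------------------------------------------------------
# pan-cancer matrix


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent Gaussian correlation giving Spearman rho_s under a Gaussian copula."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def gen_pan_cancer(cfg: SimConfig, outdir: str | Path | None = None):
    """Samples x circRNA junction counts coupled to host-gene FPKM.

    Counts are negative-binomial; for circRNAs named in ``cfg.spiked_rho``
    the count and the host-gene FPKM are coupled through a Gaussian copula
    whose latent correlation is chosen so the *continuous* marginals would
    have exactly the target Spearman rho (count discretization attenuates
    it slightly; the achieved value is part of the truth record). Returns
    (PanCancerMatrix, truth).
    """
    from .catalog import PanCancerMatrix, pan_cancer_frequency

    rng = cfg.rng("pan_cancer")
    n, c = cfg.n_samples, cfg.n_circ
    samples = [f"S{i:04d}" for i in range(n)]
    circs = [f"circ_{i:04d}" for i in range(c)]
    genes = [f"GENE{i}" for i in range(min(c, cfg.n_genes))]
    circ_to_gene = {circ: genes[i % len(genes)] for i, circ in enumerate(circs)}

    p_nb = cfg.nb_size / (cfg.nb_size + cfg.nb_mean)
    counts = np.empty((n, c), dtype=int)
    fpkm = pd.DataFrame(
        np.exp(rng.normal(cfg.fpkm_meanlog, cfg.fpkm_sdlog, size=(n, len(genes)))),
        index=samples, columns=genes,
    )
    achieved = {}
    for j, circ in enumerate(circs):
        rho = cfg.spiked_rho.get(circ)
        if rho is None:
            counts[:, j] = rng.negative_binomial(cfg.nb_size, p_nb, size=n)
            continue
        r = spearman_to_pearson_latent(rho)
        cov = np.array([[1.0, r], [r, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        u_count = stats.norm.cdf(z[:, 0])
        p_spiked = cfg.nb_size / (cfg.nb_size + cfg.nb_mean_spiked)
        counts[:, j] = stats.nbinom.ppf(u_count, cfg.nb_size, p_spiked).astype(int)
        gene = circ_to_gene[circ]
        fpkm[gene] = np.exp(cfg.fpkm_meanlog + cfg.fpkm_sdlog * z[:, 1])
        achieved[circ] = float(
            stats.spearmanr(counts[:, j], fpkm[gene]).statistic
        )

    circ_counts = pd.DataFrame(counts, index=samples, columns=circs)
    m = PanCancerMatrix(circ_counts=circ_counts, linear_expr=fpkm,
                        circ_to_gene=circ_to_gene)
    truth = {
        "rho_targets": dict(cfg.spiked_rho),
        "rho_achieved": achieved,
        "frequency": pan_cancer_frequency(m, min_reads=2).to_dict(),
        "abundance": circ_counts.sum(axis=0).to_dict(),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        release = circ_counts.stack().rename("reads").reset_index()
        release.columns = ["sample", "circ_id", "reads"]
        release["gene"] = release["circ_id"].map(circ_to_gene)
        release[["circ_id", "sample", "reads", "gene"]].to_csv(
            outdir / "release.txt", sep="\t", index=False)
        fpkm.T.to_csv(outdir / "fpkm_matrix.csv", float_format="%.6g")
        with open(outdir / "pan_cancer_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return m, truth


# ---------------------------------------------------------------------------
# toy locus


def gen_gene_model(cfg: SimConfig, outdir: str | Path | None = None):
    """A random-sequence genome with one annotated multi-exon gene.

    Exon/intron lengths come from the config (default: a long middle exon,
    the circularization substrate, flanked by long introns). Returns
    (GeneModel, genome_dict, truth) where truth carries the planted
    strand-corrected exon sequences. Writes GTF + FASTA when ``outdir`` set.
    """
    from .design import GeneModel, revcomp

    rng = cfg.rng("gene_model")
    if cfg.n_exons < 2:
        raise ValueError("need >= 2 exons")
    exon_lengths = list(cfg.exon_lengths)[: cfg.n_exons]
    intron_lengths = list(cfg.intron_lengths)[: cfg.n_exons - 1]
    while len(exon_lengths) < cfg.n_exons:
        exon_lengths.append(int(rng.integers(80, 400)))
    while len(intron_lengths) < cfg.n_exons - 1:
        intron_lengths.append(int(rng.integers(200, 1500)))

    margin = 100
    pos = margin
    exons = []
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    genome_len = pos + margin
    chrom_seq = _random_seq(rng, genome_len, cfg.gc_content)
    genome = {"chrSim": chrom_seq}
    gm = GeneModel(gene_id="GENE_SIM", chrom="chrSim", strand=cfg.locus_strand,
                   exons=exons)
    exons_tx = gm.exons_transcript_order
    planted = [
        chrom_seq[s:e] if cfg.locus_strand == "+" else revcomp(chrom_seq[s:e])
        for s, e in exons_tx
    ]
    truth = {"exon_sequences_tx_order": planted,
             "transcript_length": sum(exon_lengths)}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "locus.fa", "w") as fh:
            fh.write(">chrSim\n")
            for i in range(0, genome_len, 60):
                fh.write(chrom_seq[i:i + 60] + "\n")
        with open(outdir / "locus.gtf", "w") as fh:
            for i, (s, e) in enumerate(gm.exons, 1):
                attrs = f'gene_id "GENE_SIM"; transcript_id "GENE_SIM.t1"; exon_number "{i}";'
                fh.write(f"chrSim\tsim\texon\t{s + 1}\t{e}\t.\t{cfg.locus_strand}\t.\t{attrs}\n")
        with open(outdir / "locus_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return gm, genome, truth


# ---------------------------------------------------------------------------
# qPCR


def _ct_from_copies(copies, efficiency: float, intercept: float):
    """Ideal Ct of a well containing ``copies`` molecules: intercept - log_{1+E}(copies)."""
    return intercept - np.log(np.asarray(copies, float)) / np.log(1.0 + efficiency)


def gen_standard_series(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Dilution-series measurements at the standard decades (10^11..10^7 copies)."""
    if rng is None:
        rng = cfg.rng("qpcr")
    rows = []
    for dec in cfg.standard_decades:
        copies = 10.0 ** dec
        ideal = _ct_from_copies(copies, cfg.efficiency, cfg.ct_intercept)
        for rep in range(1, cfg.n_replicates + 1):
            rows.append({"copies": copies, "replicate": rep,
                         "ct": float(ideal + rng.normal(0.0, cfg.sigma_ct))})
    return pd.DataFrame(rows)


def gen_qpcr(cfg: SimConfig, truth_copies: dict, outdir: str | Path | None = None):
    """Ct table generated from true per-(sample, target) copy numbers.

    ``truth_copies`` maps (sample, target) -> true copies in the reaction.
    Ct = intercept - log_{1+E}(copies) + N(0, sigma_ct), independent across
    replicates. Also emits the standard dilution series for curve fitting.
    Returns (CtTable, standards_df).
    """
    from .quant import CtTable

    if not 0.7 < cfg.efficiency <= 1.1:
        raise ValueError("efficiency must be in (0.7, 1.1]")
    rng = cfg.rng("qpcr")
    rows = []
    for (sample, target), copies in sorted(truth_copies.items()):
        if copies <= 0:
            continue
        ideal = _ct_from_copies(copies, cfg.efficiency, cfg.ct_intercept)
        for rep in range(1, cfg.n_replicates + 1):
            ct_val = float(ideal + rng.normal(0.0, cfg.sigma_ct))
            flag = "ok" if ct_val <= 40.0 else "undetermined"
            rows.append({"sample": sample, "target": target, "replicate": rep,
                         "ct": min(ct_val, 40.0), "flag": flag})
    table = CtTable(pd.DataFrame(rows))
    standards = gen_standard_series(cfg, rng)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.data.to_csv(outdir / "ct_table.csv", index=False, float_format="%.6f")
        standards.to_csv(outdir / "standards.csv", index=False, float_format="%.6f")
    return table, standards


# ---------------------------------------------------------------------------
# cohort


def gen_cohort(cfg: SimConfig, outdir: str | Path | None = None):
    """Assay-call cohort derived from a latent High/Low status.

    Each sample draws a latent status (P(High) = prevalence); each assay
    reports the latent status flipped with probability ``flip_prob`` and is
    missing with probability ``missing_rate`` (independently per assay).
    Plasma circRNA concentrations come from status-specific lognormals.
    Returns (calls_df, plasma_series, truth).
    """
    rng = cfg.rng("cohort")
    samples = [f"P{i:03d}" for i in range(cfg.n_patients)]
    latent = rng.random(cfg.n_patients) < cfg.prevalence
    rows = []
    for i, sample in enumerate(samples):
        status = latent[i]
        for method in METHODS:
            if rng.random() < cfg.missing_rate:
                rows.append({"sample_id": sample, "method": method, "call": "missing"})
                continue
            observed = status if rng.random() >= cfg.flip_prob else not status
            rows.append({"sample_id": sample, "method": method,
                         "call": "positive" if observed else "negative"})
    calls = pd.DataFrame(rows)
    meanlog = np.where(latent, cfg.plasma_meanlog_high, cfg.plasma_meanlog_low)
    plasma = pd.Series(
        np.exp(rng.normal(meanlog, cfg.plasma_sdlog)), index=samples,
        name="plasma_circ_copies_per_ml",
    )
    truth = {"status": {s: ("High" if l else "Low") for s, l in zip(samples, latent)}}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        calls.to_csv(outdir / "cohort_calls.csv", index=False)
        plasma.rename_axis("sample_id").reset_index().to_csv(
            outdir / "plasma_values.csv", index=False, float_format="%.4f")
        with open(outdir / "cohort_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return calls, plasma, truth


# ---------------------------------------------------------------------------
# longitudinal


def gen_longitudinal(cfg: SimConfig, n_patients: int | None = None,
                     outdir: str | Path | None = None):
    """Longitudinal plasma series with a programmed emergence event.

    Values sit at a lognormal floor (``baseline_level``) before
    ``emergence_time`` and are scaled by ``emergence_fold`` from that
    timepoint on, with multiplicative noise of the stated CV. A parallel
    cfDNA copy-number series is co-generated with the same switch point.
    Returns (series_df, truth) where truth maps patient -> emergence time
    (None for the never-emerging control patient 0).
    """
    rng = cfg.rng("longitudinal")
    n_pat = cfg.n_patients if n_patients is None else n_patients
    sdlog = np.sqrt(np.log(1.0 + cfg.noise_cv ** 2))
    rows, truth = [], {}
    for p in range(n_pat):
        pid = f"PT{p:03d}"
        emerges = p != 0  # patient 0 is a flat control
        t_em = cfg.emergence_time if emerges else None
        truth[pid] = t_em
        for t in range(cfg.n_timepoints):
            level = cfg.baseline_level
            cnv = 2.0
            if emerges and t >= cfg.emergence_time:
                level *= cfg.emergence_fold
                cnv *= 4.0
            noise = np.exp(rng.normal(0.0, sdlog))
            rows.append({"patient_id": pid, "time": t, "measure": "plasma_circ",
                         "value": float(level * noise),
                         "treatment": "on" if t >= 2 else "baseline"})
            rows.append({"patient_id": pid, "time": t, "measure": "cfdna_cnv",
                         "value": float(cnv * np.exp(rng.normal(0.0, sdlog / 2))),
                         "treatment": "on" if t >= 2 else "baseline"})
    series = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        series.to_csv(outdir / "longitudinal.csv", index=False, float_format="%.4f")
        with open(outdir / "longitudinal_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return series, truth
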