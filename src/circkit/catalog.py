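"""Mining circRNA catalogs and pan-cancer compendia for candidate biomarkers.

This module parses circRNA catalog dumps (circBase-style BED-like files,
circAtlas-style headered TSVs) and pan-cancer junction-read releases, and
implements the candidate-prioritization statistics used to single out a
dominant circRNA at a locus: the junction ratio (circular fraction at the
back-splice site), pan-cancer detection frequency, abundance ranking with a
top-quartile flag, a circ-vs-linear Spearman correlation screen restricted to
the most abundant circRNAs, and cross-database integration (Venn membership
and species conservation).

Coordinates are 0-based half-open internally (BED convention); 1-based
inclusive dialects are converted on load.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CircRecord",
    "PanCancerMatrix",
    "CatalogIntegration",
    "load_catalog",
    "read_release",
    "read_fpkm",
    "junction_ratio",
    "pan_cancer_frequency",
    "abundance_rank",
    "circ_linear_screen",
    "integrate_catalogs",
    "venn_region_counts",
    "prioritize",
    "write_ranking",
]


@dataclass
class CircRecord:
    """One catalog entry for a circRNA back-splice junction.

    Coordinates are 0-based half-open. ``bsj_reads`` counts back-spliced
    junction reads; ``total_junction_reads`` counts all reads aligned at the
    junction site (linear + back-spliced).
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    host_gene: str | None = None
    species: str | None = None
    spliced_length: int | None = None
    bsj_reads: int | None = None
    total_junction_reads: int | None = None
    source_db: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.circ_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.circ_id}: strand must be '+' or '-'")
        if self.spliced_length is not None and self.spliced_length <= 0:
            raise ValueError(f"{self.circ_id}: spliced_length must be > 0")
        if (
            self.bsj_reads is not None
            and self.total_junction_reads is not None
            and self.bsj_reads > self.total_junction_reads
        ):
            raise ValueError(
                f"{self.circ_id}: bsj_reads ({self.bsj_reads}) exceeds "
                f"total_junction_reads ({self.total_junction_reads})"
            )

    @property
    def junction_ratio(self) -> float | None:
        if self.bsj_reads is None or self.total_junction_reads is None:
            return None
        if self.total_junction_reads == 0:
            return None
        return junction_ratio(self.bsj_reads, self.total_junction_reads)


@dataclass
class PanCancerMatrix:
    """Paired samples x circRNA junction counts and samples x gene FPKM.

    ``circ_counts``: DataFrame (samples x circRNAs) of non-negative integer
    junction-read counts. ``linear_expr``: DataFrame (samples x genes) of
    FPKM; NaN means not measured (never zero-imputed). ``circ_to_gene`` maps
    circRNA id to its host gene symbol.
    """

    circ_counts: pd.DataFrame
    linear_expr: pd.DataFrame
    circ_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        if (self.circ_counts.to_numpy() < 0).any():
            raise ValueError("circ_counts must be non-negative")
        shared = self.circ_counts.index.intersection(self.linear_expr.index)
        if len(self.circ_counts) and len(self.linear_expr) and shared.empty:
            raise ValueError("no shared samples between count and FPKM matrices")

    @property
    def shared_samples(self) -> pd.Index:
        return self.circ_counts.index.intersection(self.linear_expr.index)


@dataclass
class CatalogIntegration:
    """Cross-database membership and cross-species conservation matrices."""

    membership: pd.DataFrame  # circ x source_db, bool
    conservation: pd.DataFrame  # circ x species, bool
    ambiguities: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers

#: column maps for the supported catalog dialects
_DIALECTS = {
    "bed-like": None,  # positional, headerless
    "tsv-with-header": {
        "circ_id": "circ_id",
        "chrom": "chrom",
        "start": "start",
        "end": "end",
        "strand": "strand",
    },
}


def load_catalog(
    path,
    dialect: str = "bed-like",
    *,
    source_db: str | None = None,
    species: str | None = None,
    one_based: bool = False,
    column_map: dict[str, str] | None = None,
):
    """Read a circRNA catalog flat file into records.

    Parameters
    ----------
    path : str or Path
        Catalog file.
    dialect : {"bed-like", "tsv-with-header"}
        ``bed-like``: headerless, tab-separated, columns
        chrom/start/end/name/score/strand[/bsj_reads/total_junction_reads],
        0-based half-open (set ``one_based=True`` for 1-based inclusive
        dumps). ``tsv-with-header``: first line names columns; ``column_map``
        overrides the default field->column names; optional columns
        (host_gene, species, spliced_length, bsj_reads,
        total_junction_reads) are picked up when present.
    one_based : bool
        Input coordinates are 1-based inclusive; converted to 0-based
        half-open (start-1, end).

    Returns
    -------
    (records, errors) : (list[CircRecord], list[dict])
        Malformed rows are reported in ``errors`` (line number, message,
        raw text), never silently dropped.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use one of {sorted(_DIALECTS)}")

    records: list[CircRecord] = []
    errors: list[dict] = []

    def _coords(start, end):
        start, end = int(start), int(end)
        if one_based:
            start -= 1
        return start, end

    if dialect == "bed-like":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                try:
                    if len(parts) < 3:
                        raise ValueError("fewer than 3 columns")
                    start, end = _coords(parts[1], parts[2])
                    name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
                    strand = parts[5] if len(parts) > 5 else "+"
                    bsj = int(parts[6]) if len(parts) > 6 and parts[6] != "." else None
                    tot = int(parts[7]) if len(parts) > 7 and parts[7] != "." else None
                    records.append(
                        CircRecord(
                            circ_id=name,
                            chrom=parts[0],
                            start=start,
                            end=end,
                            strand=strand,
                            bsj_reads=bsj,
                            total_junction_reads=tot,
                            source_db=source_db,
                            species=species,
                        )
                    )
                except (ValueError, IndexError) as exc:
                    errors.append({"line": lineno, "error": str(exc), "raw": line})
        return records, errors

    # headered TSV
    cmap = dict(_DIALECTS["tsv-with-header"])
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("circ_id", "chrom", "start", "end") if cmap[c] not in df.columns]
    if missing:
        raise ValueError(f"column map unresolvable: missing {missing} in {path}")
    optional = ("host_gene", "species", "spliced_length", "bsj_reads", "total_junction_reads")
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        row = row._asdict()
        try:
            start, end = _coords(row[cmap["start"]], row[cmap["end"]])
            kwargs = {}
            for fieldname in optional:
                col = cmap.get(fieldname, fieldname)
                if col in row and pd.notna(row[col]):
                    val = row[col]
                    if fieldname in ("spliced_length", "bsj_reads", "total_junction_reads"):
                        val = int(float(val))
                    kwargs[fieldname] = val
            strand_col = cmap.get("strand", "strand")
            strand = row.get(strand_col, "+")
            if pd.isna(strand):
                strand = "+"
            records.append(
                CircRecord(
                    circ_id=row[cmap["circ_id"]],
                    chrom=row[cmap["chrom"]],
                    start=start,
                    end=end,
                    strand=strand,
                    source_db=source_db,
                    **{"species": species, **kwargs},
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append({"line": lineno, "error": str(exc), "raw": str(row)})
    return records, errors


def read_release(path) -> pd.DataFrame:
    """Read a pan-cancer junction-read release (long-format TSV).

    Expected columns: circ_id, sample, reads (one row per circRNA-sample
    observation); extra columns (chrom, start, end, gene) pass through.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"circ_id", "sample", "reads"}
    if not required.issubset(df.columns):
        raise ValueError(f"release file missing columns {required - set(df.columns)}")
    return df


def read_fpkm(path) -> pd.DataFrame:
    """Read a genes x samples FPKM CSV; returns samples x genes."""
    df = pd.read_csv(path, index_col=0)
    return df.T


def build_matrix(release: pd.DataFrame, fpkm: pd.DataFrame,
                 circ_to_gene: dict[str, str] | None = None) -> PanCancerMatrix:
    """Pivot a long-format release into a PanCancerMatrix paired with FPKM."""
    counts = (
        release.pivot_table(index="sample", columns="circ_id", values="reads",
                            aggfunc="sum", fill_value=0)
        .astype(int)
    )
    if circ_to_gene is None:
        if "gene" not in release.columns:
            raise ValueError("need circ_to_gene map or a 'gene' column in the release")
        circ_to_gene = dict(
            release[["circ_id", "gene"]].drop_duplicates().itertuples(index=False)
        )
    return PanCancerMatrix(circ_counts=counts, linear_expr=fpkm, circ_to_gene=circ_to_gene)


# ---------------------------------------------------------------------------
# statistics


def junction_ratio(bsj_reads: int, total_junction_reads: int) -> float | None:
    """Fraction of junction-site reads that are back-spliced.

    Returns ``bsj/total`` in [0, 1]; ``None`` (undefined) when no reads
    align to the junction site at all.
    """
    if bsj_reads < 0 or total_junction_reads < 0:
        raise ValueError("read counts must be non-negative")
    if bsj_reads > total_junction_reads:
        raise ValueError(
            f"bsj_reads ({bsj_reads}) cannot exceed total_junction_reads "
            f"({total_junction_reads})"
        )
    if total_junction_reads == 0:
        return None
    return bsj_reads / total_junction_reads


def pan_cancer_frequency(m: PanCancerMatrix, min_reads: int = 2) -> pd.Series:
    """Per circRNA, the number of tumor samples with >= ``min_reads`` junction reads.

    The default threshold of 2 reads reflects the standard requirement of at
    least two junction reads for a circRNA to count as detected in a sample.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if m.circ_counts.empty:
        return pd.Series(dtype=int, name="frequency")
    return (m.circ_counts >= min_reads).sum(axis=0).rename("frequency")


def abundance_rank(m: PanCancerMatrix) -> pd.DataFrame:
    """Rank circRNAs by total junction reads summed over all samples.

    Returns a DataFrame indexed by circ_id with columns ``abundance``
    (column sum), ``rank`` (1 = most abundant; ties broken by circ_id
    lexicographic order) and ``quartile`` (True iff abundance >= the 75th
    percentile, linear-interpolation definition, inclusive).
    """
    if m.circ_counts.empty:
        raise ValueError("empty count matrix")
    abundance = m.circ_counts.sum(axis=0).rename("abundance")
    order = abundance.to_frame().reset_index(names="circ_id")
    order = order.sort_values(["abundance", "circ_id"], ascending=[False, True])
    order["rank"] = np.arange(1, len(order) + 1)
    q75 = np.percentile(abundance.to_numpy(), 75)
    order["quartile"] = order["abundance"] >= q75
    return order.set_index("circ_id")


def circ_linear_screen(
    m: PanCancerMatrix,
    ranking: pd.DataFrame,
    detection_min: int = 1,
) -> pd.DataFrame:
    """Spearman circ-vs-host-linear correlation for top-quartile circRNAs.

    For each quartile-flagged circRNA the correlation is computed over
    samples where the circRNA has >= ``detection_min`` junction reads and the
    host gene FPKM is non-missing (average ranks for ties). circRNAs outside
    the top quartile, with an unmapped host gene, or with fewer than 3 usable
    samples get a missing rho with a ``reason``.
    """
    out = ranking.copy()
    out["rho"] = np.nan
    out["n_samples_used"] = 0
    out["reason"] = ""
    shared = m.shared_samples
    for circ_id in out.index:
        if not out.at[circ_id, "quartile"]:
            out.at[circ_id, "reason"] = "below top quartile"
            continue
        gene = m.circ_to_gene.get(circ_id)
        if gene is None or gene not in m.linear_expr.columns:
            out.at[circ_id, "reason"] = "host gene not in FPKM matrix"
            continue
        counts = m.circ_counts.loc[shared, circ_id]
        fpkm = m.linear_expr.loc[shared, gene]
        mask = (counts >= detection_min) & fpkm.notna()
        n = int(mask.sum())
        out.at[circ_id, "n_samples_used"] = n
        if n < 3:
            out.at[circ_id, "reason"] = f"only {n} usable samples (< 3)"
            continue
        rho = stats.spearmanr(counts[mask], fpkm[mask]).statistic
        out.at[circ_id, "rho"] = rho
    return out


# ---------------------------------------------------------------------------
# cross-database integration


def _match_key(rec: CircRecord, tolerance: int, clusters: list[dict]) -> int | None:
    for i, cl in enumerate(clusters):
        if (
            rec.chrom == cl["chrom"]
            and rec.strand == cl["strand"]
            and abs(rec.start - cl["start"]) <= tolerance
            and abs(rec.end - cl["end"]) <= tolerance
        ):
            return i
    return None


def integrate_catalogs(
    catalogs: list[tuple[str, list[CircRecord]]],
    match_tolerance: int = 0,
) -> CatalogIntegration:
    """Match circRNAs across source databases by genomic interval.

    Records match when chrom and strand agree and both endpoints are within
    ``match_tolerance`` nucleotides. Records with identical coordinates but
    conflicting strands are kept separate and flagged as ambiguities.
    Membership is permutation-invariant to catalog input order: records are
    pooled and clustered in a canonical (chrom, start, end, strand) sort.
    """
    if not catalogs:
        raise ValueError("need at least one catalog")
    pooled: list[tuple[str, CircRecord]] = [
        (src, rec) for src, recs in catalogs for rec in recs
    ]
    pooled.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end, t[1].strand, t[0]))

    clusters: list[dict] = []
    ambiguities: list[str] = []
    for src, rec in pooled:
        idx = _match_key(rec, match_tolerance, clusters)
        if idx is None:
            for cl in clusters:
                if (
                    rec.chrom == cl["chrom"]
                    and rec.start == cl["start"]
                    and rec.end == cl["end"]
                    and rec.strand != cl["strand"]
                ):
                    ambiguities.append(
                        f"{rec.chrom}:{rec.start}-{rec.end} seen on both strands"
                    )
            clusters.append(
                {
                    "chrom": rec.chrom,
                    "start": rec.start,
                    "end": rec.end,
                    "strand": rec.strand,
                    "ids": [rec.circ_id],
                    "sources": {src},
                    "species": {rec.species} if rec.species else set(),
                }
            )
        else:
            clusters[idx]["sources"].add(src)
            clusters[idx]["ids"].append(rec.circ_id)
            if rec.species:
                clusters[idx]["species"].add(rec.species)

    sources = sorted({src for src, _ in catalogs})
    all_species = sorted({sp for cl in clusters for sp in cl["species"]})
    names = [cl["ids"][0] for cl in clusters]
    membership = pd.DataFrame(
        [[s in cl["sources"] for s in sources] for cl in clusters],
        index=names,
        columns=sources,
    )
    conservation = pd.DataFrame(
        [[sp in cl["species"] for sp in all_species] for cl in clusters],
        index=names,
        columns=all_species,
    )
    return CatalogIntegration(membership=membership, conservation=conservation,
                              ambiguities=sorted(set(ambiguities)))


def venn_region_counts(integration: CatalogIntegration) -> dict[frozenset, int]:
    """Counts of circRNAs per Venn region (exact source-set combination).

    The counts over all non-empty regions sum to the number of distinct
    circRNAs.
    """
    counts: dict[frozenset, int] = {}
    sources = list(integration.membership.columns)
    for r in range(1, len(sources) + 1):
        for combo in itertools.combinations(sources, r):
            counts[frozenset(combo)] = 0
    for _, row in integration.membership.iterrows():
        region = frozenset(c for c in sources if row[c])
        if region:
            counts[region] += 1
    return counts


def prioritize(
    ranking: pd.DataFrame,
    integration: CatalogIntegration | None = None,
    junction_ratios: pd.Series | None = None,
) -> pd.DataFrame:
    """Order candidate circRNAs for follow-up.

    Sort key (all descending): number of supporting databases, total
    abundance, mean junction ratio, conservation breadth (number of species);
    ties broken by circ_id ascending. A candidate that strictly dominates all
    others on every axis is therefore first. With no integration data the
    order falls back to abundance alone.
    """
    df = pd.DataFrame(index=ranking.index.copy())
    df["abundance"] = ranking["abundance"]
    if integration is not None and not integration.membership.empty:
        df["db_support"] = integration.membership.sum(axis=1).reindex(df.index).fillna(0)
        df["conservation_breadth"] = (
            integration.conservation.sum(axis=1).reindex(df.index).fillna(0)
        )
    else:
        df["db_support"] = 0
        df["conservation_breadth"] = 0
    df["mean_junction_ratio"] = (
        junction_ratios.reindex(df.index) if junction_ratios is not None else 0.0
    )
    df["mean_junction_ratio"] = df["mean_junction_ratio"].fillna(0.0)
    df = df.reset_index(names="circ_id").sort_values(
        ["db_support", "abundance", "mean_junction_ratio", "conservation_breadth", "circ_id"],
        ascending=[False, False, False, False, True],
    )
    df["priority"] = np.arange(1, len(df) + 1)
    return df.set_index("circ_id")


# ---------------------------------------------------------------------------
# writers


def write_ranking(screen: pd.DataFrame, path) -> None:
    """Write the ranking/screen table as TSV (circ_id first column)."""
    screen.to_csv(path, sep="\t", index_label="circ_id")


def write_venn(counts: dict[frozenset, int], path) -> None:
    rows = [
        {"region": "&".join(sorted(region)), "count": n}
        for region, n in sorted(counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
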