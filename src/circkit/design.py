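"""Back-splice-junction assay design.

A circRNA is a covalently closed molecule: the 3' end of its last exon is
ligated to the 5' end of its first exon (the back-splice junction, BSJ).
Assays that are specific for the circle must interrogate that junction,
because every other position also exists on the linear transcript. This
module builds circular sequences from gene models, rotates them into a
BSJ-centered linear pseudo-reference, classifies primer pairs as convergent
(amplify the linear template) or divergent (amplify only across a circular
junction), designs junction-spanning (JS) primers and padlock-probe arms,
predicts the rolling-circle concatemer amplicon ladder of divergent PCR,
and runs an exact-match in-silico PCR over linear and circular templates.

Primer binding uses a perfect-match model throughout: a primer binds the
plus strand of a template wherever the primer string occurs verbatim, and
the minus strand wherever its reverse complement occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "CircIsoform",
    "PrimerPair",
    "PadlockAssay",
    "read_fasta",
    "read_gene_models",
    "build_circ_sequence",
    "build_bsj_reference",
    "classify_primer_pair",
    "design_junction_assay",
    "predict_divergent_amplicons",
    "in_silico_pcr",
    "wallace_tm",
]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    s = seq.upper()
    at = s.count("A") + s.count("T")
    gc = s.count("G") + s.count("C")
    return 2.0 * at + 4.0 * gc


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s) if seq else 0.0


def max_homopolymer(seq: str) -> int:
    best = run = 0
    prev = None
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


@dataclass
class GeneModel:
    """Exon structure of one gene on a genome.

    ``exons`` are (start, end) 0-based half-open genomic intervals, sorted by
    genomic position and non-overlapping. Exon indices passed to
    :func:`build_circ_sequence` are in *transcript* order (5'->3' on the
    coding strand), i.e. reversed genomic order for minus-strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for (s, e) in self.exons:
            if e - s < 1:
                raise ValueError(f"{self.gene_id}: exon length < 1 at ({s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")

    @property
    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class CircIsoform:
    """A circularized exon block with its spliced, strand-corrected sequence.

    ``circ_sequence`` is written 5'->3' starting at the first included exon;
    position 0 is the base immediately downstream of the BSJ and position
    L-1 the base immediately upstream of it. Any rotation of the string
    denotes the same molecule.
    """

    gene_id: str
    exon_block: tuple[int, ...]
    circ_sequence: str

    @property
    def length(self) -> int:
        return len(self.circ_sequence)

    @property
    def doubled(self) -> str:
        """Linearized double-pass sequence; every circular k-mer (k <= L) occurs here."""
        return self.circ_sequence + self.circ_sequence


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    orientation_class: str | None = None  # convergent | divergent | invalid
    junction_spanning: bool = False
    min_overlap: int | None = None
    notes: str = ""

    @property
    def tm(self) -> tuple[float, float]:
        return (wallace_tm(self.forward), wallace_tm(self.reverse))


@dataclass
class PadlockAssay:
    """Padlock probe + RCA detection design for one BSJ.

    The padlock's two arms are reverse complements of two adjacent target
    windows that together span the BSJ; ligation of the annealed probe
    therefore requires the back-spliced (circular) junction. The LNA primer
    primes reverse transcription downstream of the junction, and the
    decorator probe hybridizes the rolling-circle product via its complement
    embedded in the padlock backbone.
    """

    lna_primer: str
    arm_5p: str
    arm_3p: str
    decorator: str
    target_window: str  # BSJ-spanning window the arms anneal to

    def ligated_probe(self) -> str:
        """In-silico ligation: 5' arm followed by 3' arm."""
        return self.arm_5p + self.arm_3p


DECORATOR = "TGCGTCTATTTAGTGGAGCC"  # constant readout tag, arbitrary fixed sequence


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_models(gtf_path) -> dict[str, GeneModel]:
    """Parse exon records from a GTF into GeneModels (1-based inclusive -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes.get("gene_id", ["?"])[0]
        g = genes.setdefault(gid, {"chrom": exon.seqid, "strand": exon.strand, "exons": []})
        g["exons"].append((exon.start - 1, exon.end))
    return {
        gid: GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                       exons=sorted(g["exons"]))
        for gid, g in genes.items()
    }


# ---------------------------------------------------------------------------
# circle construction


def build_circ_sequence(gm: GeneModel, exon_block, genome: dict[str, str]) -> CircIsoform:
    """Splice a contiguous exon block into a circular isoform sequence.

    ``exon_block`` indexes exons in transcript order (0-based). Exons are
    concatenated in transcript order; on the minus strand each exon is
    reverse-complemented. The resulting string starts at the 5' end of the
    first included exon, so the BSJ sits between the last and first
    character of the (circular) string.
    """
    block = tuple(exon_block)
    if not block:
        raise ValueError("exon_block is empty")
    exons_tx = gm.exons_transcript_order
    for i in block:
        if not 0 <= i < len(exons_tx):
            raise IndexError(f"exon index {i} out of range for {gm.gene_id}")
    if list(block) != list(range(block[0], block[-1] + 1)):
        raise ValueError(f"exon_block {block} is not contiguous in transcript order")
    chrom_seq = genome[gm.chrom]
    parts = []
    for i in block:
        s, e = exons_tx[i]
        exon_seq = chrom_seq[s:e]
        parts.append(revcomp(exon_seq) if gm.strand == "-" else exon_seq)
    return CircIsoform(gene_id=gm.gene_id, exon_block=block, circ_sequence="".join(parts))


def build_bsj_reference(iso: CircIsoform, flank: int) -> str:
    """Rotate the circle into a linear pseudo-reference centered on the BSJ.

    Returns the last ``flank`` nt of the circular sequence followed by the
    first ``flank`` nt, so the BSJ is at string position ``flank`` (0-based).
    """
    if not 1 <= flank <= iso.length:
        raise ValueError(f"flank must be in [1, {iso.length}]")
    s = iso.circ_sequence
    return s[iso.length - flank:] + s[:flank]


# ---------------------------------------------------------------------------
# primer binding and classification


def _binding_sites(primer: str, template: str) -> tuple[list[int], list[int]]:
    """All exact-match sites of a primer on a linear template.

    Returns (plus_sites, minus_sites): start positions where the primer
    itself occurs (primer anneals to the minus strand, extends rightward)
    and where its reverse complement occurs (primer anneals to the plus
    strand, extends leftward).
    """
    def find_all(needle: str, hay: str) -> list[int]:
        out, i = [], hay.find(needle)
        while i != -1:
            out.append(i)
            i = hay.find(needle, i + 1)
        return out

    return find_all(primer, template), find_all(revcomp(primer), template)


def classify_primer_pair(pair: PrimerPair, template: str) -> str:
    """Classify a primer pair as convergent or divergent on a linear template.

    Each primer must have exactly one perfect-match site (counting both
    orientations); the pair must bind opposite strands. Convergent means the
    3' ends point toward each other (plus-strand primer upstream of the
    minus-strand site); divergent means they point away. Anything else is
    ``invalid``. The result is symmetric under swapping the forward/reverse
    labels.
    """
    sites = {}
    for label, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
        plus, minus = _binding_sites(primer, template)
        total = len(plus) + len(minus)
        if total == 0:
            pair.notes = f"{label} primer has no binding site"
            return "invalid"
        if total > 1:
            pair.notes = f"{label} primer has {total} binding sites (ambiguous)"
            return "invalid"
        sites[label] = ("+", plus[0], len(primer)) if plus else ("-", minus[0], len(primer))
    (s1, p1, l1), (s2, p2, l2) = sites["forward"], sites["reverse"]
    if s1 == s2:
        pair.notes = "both primers bind the same strand"
        return "invalid"
    plus_pos = p1 if s1 == "+" else p2
    minus_pos = p2 if s1 == "+" else p1
    cls = "convergent" if plus_pos <= minus_pos else "divergent"
    pair.orientation_class = cls
    return cls


# ---------------------------------------------------------------------------
# junction assay design


def _window_ok(seq: str, gc_min=0.30, gc_max=0.70, max_run=5) -> bool:
    return gc_min <= gc_fraction(seq) <= gc_max and max_homopolymer(seq) <= max_run


def design_junction_assay(
    iso: CircIsoform,
    primer_len: int = 20,
    min_overlap: int = 6,
    arm_len: int = 15,
    reverse_gap: int = 5,
) -> tuple[PrimerPair, PadlockAssay]:
    """Design a junction-spanning primer pair and a padlock probe for one circle.

    The JS forward primer straddles the BSJ with at least ``min_overlap``
    nt on each side; the reverse primer anneals to the minus strand of the
    circle downstream of the forward primer. Both are screened for GC
    content in [30%, 70%] and homopolymers shorter than 6, must bind the
    circle exactly once, and the JS primer must be absent from the
    un-rotated linear spliced sequence. The padlock arms are reverse
    complements of the two adjacent windows flanking the BSJ, so their
    in-silico ligation reconstructs the reverse complement of the whole
    BSJ-spanning target window.
    """
    if min_overlap < 4:
        raise ValueError("min_overlap must be >= 4")
    L = iso.length
    if L < primer_len + min_overlap:
        raise ValueError(f"circle too short ({L} nt) for primer_len={primer_len}")
    s = iso.circ_sequence
    doubled = iso.doubled

    violations: list[str] = []
    fwd = None
    fwd_upstream = None  # nt of the primer upstream of the BSJ
    for k in range(min_overlap, primer_len - min_overlap + 1):
        cand = s[L - k:] + s[: primer_len - k]
        if not _window_ok(cand):
            violations.append(f"JS window k={k}: GC/homopolymer constraint")
            continue
        if cand in s:  # must not exist on the linear molecule
            violations.append(f"JS window k={k}: occurs in linear sequence")
            continue
        plus, minus = _binding_sites(cand, doubled)
        if len([p for p in plus if p < L]) != 1 or minus:
            violations.append(f"JS window k={k}: ambiguous on circle")
            continue
        fwd, fwd_upstream = cand, k
        break
    if fwd is None:
        raise ValueError("no junction-spanning window satisfies constraints: "
                         + "; ".join(violations[:5]))

    # reverse primer: minus-strand window downstream of the forward 3' end
    fwd_end = primer_len - fwd_upstream  # circle position just past the fwd 3' end
    rev = None
    for gap in range(reverse_gap, L - primer_len):
        a = fwd_end + gap
        window = doubled[a:a + primer_len]
        cand = revcomp(window)
        if not _window_ok(cand):
            continue
        plus, minus = _binding_sites(cand, doubled)
        if plus or len([p for p in minus if p < L]) != 1:
            continue
        rev = cand
        break
    if rev is None:
        raise ValueError("no reverse-primer window satisfies GC/homopolymer constraints")

    pair = PrimerPair(forward=fwd, reverse=rev, orientation_class="divergent",
                      junction_spanning=True, min_overlap=min_overlap)

    # padlock: arms anneal adjacently across the BSJ
    target = s[L - arm_len:] + s[:arm_len]
    rc = revcomp(target)
    padlock = PadlockAssay(
        lna_primer=revcomp(doubled[arm_len + reverse_gap: arm_len + reverse_gap + primer_len]),
        arm_5p=rc[:arm_len],          # revcomp of the downstream half
        arm_3p=rc[arm_len:],          # revcomp of the upstream half
        decorator=DECORATOR,
        target_window=target,
    )
    return pair, padlock


# ---------------------------------------------------------------------------
# amplicon prediction


def predict_divergent_amplicons(
    pair: PrimerPair, iso: CircIsoform, max_rounds: int = 3
) -> dict[int, int]:
    """Predicted divergent-PCR amplicon ladder on a circular template.

    Reverse transcription around a circle is rolling: each extra pass adds
    one full circumference L, so round k >= 1 has length
    ``length(1) + (k-1)*L``. Round-1 length is the circular distance from
    the forward primer's 5' base, around the BSJ, to the reverse primer's
    5' base, inclusive of both. Returns {k: length_bp}; empty if either
    primer does not bind the circle exactly once.
    """
    L = iso.length
    doubled = iso.doubled

    def circle_sites(primer):
        plus, minus = _binding_sites(primer, doubled)
        return ([p for p in plus if p < L], [p for p in minus if p < L])

    f_plus, f_minus = circle_sites(pair.forward)
    r_plus, r_minus = circle_sites(pair.reverse)
    # one primer on each strand, each binding once
    if len(f_plus) == 1 and not f_minus and len(r_minus) == 1 and not r_plus:
        fwd5 = f_plus[0]
        rev5 = (r_minus[0] + len(pair.reverse) - 1) % L
    elif len(f_minus) == 1 and not f_plus and len(r_plus) == 1 and not r_minus:
        fwd5 = r_plus[0]
        rev5 = (f_minus[0] + len(pair.forward) - 1) % L
    else:
        return {}
    round1 = (rev5 - fwd5) % L + 1
    return {k: round1 + (k - 1) * L for k in range(1, max_rounds + 1)}


def in_silico_pcr(
    pair: PrimerPair,
    templates: dict[str, tuple[str, bool]],
    max_len: int = 2000,
) -> dict[str, list[dict]]:
    """Exact-match PCR product enumeration over named templates.

    ``templates`` maps name -> (sequence, is_circular). A product forms
    between any plus-strand site of either primer and any downstream
    minus-strand site of either primer, with length <= ``max_len``. For
    circular templates, sites are enumerated on the doubled sequence with
    the plus site restricted to the first pass and product length capped at
    one circumference (single-pass products; concatemer rounds are handled
    by :func:`predict_divergent_amplicons`).

    Reproduces the junction specificity truth table: a convergent pair
    yields products on linear gDNA/cDNA; a divergent junction-spanning pair
    yields products only on the circular template.
    """
    results: dict[str, list[dict]] = {}
    primers = {"forward": pair.forward, "reverse": pair.reverse}
    for name, (seq, circular) in templates.items():
        search = seq + seq if circular else seq
        L = len(seq)
        products = []
        seen = set()
        sites = {lab: _binding_sites(p, search) for lab, p in primers.items()}
        for lab_f, (plus, _) in sites.items():
            for i in plus:
                if circular and i >= L:
                    continue
                for lab_r, (_, minus) in sites.items():
                    for j in minus:
                        end = j + len(primers[lab_r])
                        length = end - i
                        if length < max(len(primers[lab_f]), len(primers[lab_r])):
                            continue
                        if length > max_len or (circular and length > L):
                            continue
                        key = (i % L if circular else i, end % L if circular else end, length)
                        if key in seen:
                            continue
                        seen.add(key)
                        products.append(
                            {"start": key[0], "end": key[1], "length": length,
                             "plus_primer": lab_f, "minus_primer": lab_r}
                        )
        results[name] = sorted(products, key=lambda d: (d["start"], d["length"]))
    return results
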