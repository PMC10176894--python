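"""Quantitative PCR and digital PCR endpoint calculations.

Converts raw Ct tables and dPCR copies/µl readouts into the quantitative
endpoints of a circRNA biomarker workflow:

* relative expression by the 2^-ddCt method against a reference gene and a
  calibrator sample;
* exonuclease-resistance fractions (mock vs RNase-R-treated Ct shift);
* absolute quantification via in-vitro-transcribed standards: molar mass
  from sequence, mass -> copies, standard-curve fit (Ct vs log10 copies),
  copies per µg of total RNA, and copies per cell given the total-RNA yield
  per cell (default 7.72 pg);
* exon-skipped transcript abundance by subtraction of canonical from total
  transcript copies;
* qPCR gene copy number normalized to a centromeric reference (aneuploidy)
  and a parental sample, with a twofold amplification threshold;
* first-order RNA decay half-life from a transcription-block time course;
* conversion of dPCR copies/µl of input cDNA into copies/ml of plasma
  through the extraction/RT volume chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "StandardCurve",
    "RnaStandard",
    "VolumeChain",
    "read_ct_table",
    "load_volume_chain",
    "relative_expression",
    "rnase_r_resistance",
    "molar_mass",
    "mass_to_copies",
    "fit_standard_curve",
    "copies_from_ct",
    "copies_per_cell",
    "exon_skip_abundance",
    "gcn_qpcr",
    "decay_half_life",
    "plasma_copies_per_ml",
]

AVOGADRO = 6.02214076e23

#: ribonucleotide-monophosphate residue masses, g/mol
RESIDUE_MASS = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}
WATER_MASS = 18.02
#: extra mass of the 5' end group on a linear molecule, beyond the residue sum
END_GROUP_EXTRA = {"5'-OH": 0.0, "5'-monophosphate": 79.98, "5'-triphosphate": 159.0}

#: default total RNA content of one cell, picograms
PG_RNA_PER_CELL = 7.72

MAX_CYCLES = 40.0


@dataclass
class CtTable:
    """Long-format qPCR results: one row per (sample, target, replicate).

    ``flag`` is "ok" or "undetermined" (no amplification within
    ``max_cycles``). Undetermined wells are treated per the policy of each
    downstream operation: dropped by default, or imputed at ``max_cycles``.
    """

    data: pd.DataFrame
    max_cycles: float = MAX_CYCLES

    def __post_init__(self) -> None:
        required = {"sample", "target", "ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"Ct table missing columns {required - set(self.data.columns)}")
        df = self.data.copy()
        if "replicate" not in df.columns:
            df["replicate"] = 1
        if "flag" not in df.columns:
            df["flag"] = "ok"
        ok = df["flag"] == "ok"
        bad = ok & ((df["ct"] <= 0) | (df["ct"] > self.max_cycles))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} Ct values outside (0, {self.max_cycles}]"
            )
        self.data = df

    def mean_ct(self, undetermined: str = "drop") -> pd.DataFrame:
        """Replicate-averaged Ct per (sample, target).

        ``undetermined='drop'`` excludes flagged wells; ``'impute_max'``
        substitutes ``max_cycles``.
        """
        df = self.data.copy()
        if undetermined == "drop":
            df = df[df["flag"] == "ok"]
        elif undetermined == "impute_max":
            df.loc[df["flag"] != "ok", "ct"] = self.max_cycles
        else:
            raise ValueError("undetermined policy must be 'drop' or 'impute_max'")
        return df.groupby(["sample", "target"], as_index=False)["ct"].mean()


def read_ct_table(path, max_cycles: float = MAX_CYCLES) -> CtTable:
    """Read a Ct CSV with columns sample, target, replicate, ct[, flag]."""
    return CtTable(pd.read_csv(path), max_cycles=max_cycles)


@dataclass
class StandardCurve:
    """Linear fit of Ct against log10(copies) for a dilution series."""

    slope: float
    intercept: float
    r_squared: float
    points: pd.DataFrame = field(repr=False, default=None)

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class RnaStandard:
    """An in-vitro-transcribed (or synthetic circular) RNA quantification standard."""

    sequence: str
    topology: str = "linear"  # linear | circular
    end_group: str = "5'-triphosphate"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be 'linear' or 'circular'")
        if self.end_group not in END_GROUP_EXTRA:
            raise ValueError(f"end_group must be one of {sorted(END_GROUP_EXTRA)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def molar_mass(self) -> float:
        return molar_mass(self)


@dataclass
class VolumeChain:
    """Liquid-handling chain from plasma to the dPCR reaction.

    Defaults mirror a standard cell-free RNA workflow: RNA from 1 ml plasma
    eluted in 100 µl, 15 µl of that into a 20 µl reverse transcription, with
    the dPCR result reported per µl of input cDNA (so the cDNA volume loaded
    on the chip cancels out).
    """

    plasma_volume_ml: float = 1.0
    rna_eluate_volume_ul: float = 100.0
    rna_volume_into_rt_ul: float = 15.0
    rt_final_volume_ul: float = 20.0
    cdna_loaded_ul: float = 5.0

    def __post_init__(self) -> None:
        vols = (self.plasma_volume_ml, self.rna_eluate_volume_ul,
                self.rna_volume_into_rt_ul, self.rt_final_volume_ul,
                self.cdna_loaded_ul)
        if any(v <= 0 for v in vols):
            raise ValueError("all volumes must be > 0")
        if self.rna_volume_into_rt_ul > self.rna_eluate_volume_ul:
            raise ValueError("cannot load more RNA than was eluted")

    @property
    def multiplier(self) -> float:
        """copies/ml plasma per (copies/µl input cDNA)."""
        rna_fraction = self.rna_volume_into_rt_ul / self.rna_eluate_volume_ul
        return self.rt_final_volume_ul / rna_fraction / self.plasma_volume_ml


def load_volume_chain(path) -> VolumeChain:
    """Read a VolumeChain from a YAML key-value config file.

    Recognized keys match the VolumeChain field names; missing keys keep
    their defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in VolumeChain.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown volume-chain keys: {sorted(unknown)}")
    return VolumeChain(**data)


# ---------------------------------------------------------------------------
# relative quantification


def relative_expression(
    ct: CtTable,
    target: str,
    reference_gene: str,
    calibrator_sample: str,
    undetermined: str = "drop",
) -> tuple[pd.Series, list[str]]:
    """Fold change per sample by the 2^-ddCt method.

    Replicates are averaged (arithmetic mean of Ct) before dCt = Ct_target -
    Ct_reference; ddCt subtracts the calibrator sample's dCt, so the
    calibrator's fold is exactly 1. Samples lacking a reference-gene Ct are
    skipped and reported.
    """
    mean = ct.mean_ct(undetermined)
    wide = mean.pivot(index="sample", columns="target", values="ct")
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    if calibrator_sample not in wide.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    skipped = []
    dct = wide[target] - wide[reference_gene]
    for sample in wide.index:
        if pd.isna(wide.at[sample, reference_gene]):
            skipped.append(f"{sample}: reference gene not measured")
        elif pd.isna(wide.at[sample, target]):
            skipped.append(f"{sample}: target not measured")
    calib_dct = dct.loc[calibrator_sample]
    if pd.isna(calib_dct):
        raise ValueError("calibrator sample lacks target or reference Ct")
    fold = np.power(2.0, -(dct - calib_dct)).dropna().rename("fold")
    return fold, skipped


def rnase_r_resistance(
    ct: CtTable, mock_label: str, treated_label: str, undetermined: str = "drop"
) -> pd.Series:
    """Fraction of each target surviving exonuclease treatment.

    ``2^-(Ct_treated - Ct_mock)`` per target; values above 1 report apparent
    enrichment (expected for circles after linear RNA is degraded and the
    same RNA mass is loaded). Targets missing either condition are skipped.
    """
    mean = ct.mean_ct(undetermined)
    wide = mean.pivot(index="target", columns="sample", values="ct")
    for label in (mock_label, treated_label):
        if label not in wide.columns:
            raise ValueError(f"condition {label!r} not in table")
    frac = np.power(2.0, -(wide[treated_label] - wide[mock_label]))
    return frac.dropna().rename("fraction_remaining")


# ---------------------------------------------------------------------------
# absolute quantification


def molar_mass(std: RnaStandard) -> float:
    """Molecular weight of an RNA standard computed from its sequence.

    Sum of nucleotide-monophosphate residue masses; a circular molecule has
    no free ends so nothing is added. A linear molecule adds one water (the
    terminal hydroxyls) plus the extra mass of its 5' end group (default
    5'-triphosphate, the product of in vitro transcription).
    """
    seq = std.sequence.upper().replace("T", "U")
    try:
        mass = sum(RESIDUE_MASS[b] for b in seq)
    except KeyError as exc:
        raise ValueError(f"non-ACGU character in sequence: {exc.args[0]!r}") from exc
    if std.topology == "linear":
        mass += WATER_MASS + END_GROUP_EXTRA[std.end_group]
    return mass


def composition_for_mass(length: int, target_mass: float, topology: str = "circular",
                         end_group: str = "5'-triphosphate") -> RnaStandard:
    """Find a base composition of given length whose molar mass approximates a target.

    Useful to check a reported standard mass for internal consistency when
    the sequence itself is unavailable: starts from an all-U molecule and
    greedily swaps U for G, A or C (mass increments +39.04, +23.04, -0.99
    g/mol) until the computed mass is as close to the target as those
    increments allow. Returns a synthetic RnaStandard with that composition.
    """
    base = RnaStandard("U" * length, topology=topology, end_group=end_group)
    deficit = target_mass - molar_mass(base)
    inc_g = RESIDUE_MASS["G"] - RESIDUE_MASS["U"]
    inc_a = RESIDUE_MASS["A"] - RESIDUE_MASS["U"]
    n_g = min(length, max(0, int(deficit / inc_g)))
    deficit -= n_g * inc_g
    n_a = min(length - n_g, max(0, int(deficit / inc_a)))
    seq = "G" * n_g + "A" * n_a + "U" * (length - n_g - n_a)
    return RnaStandard(seq, topology=topology, end_group=end_group)


def mass_to_copies(mass_g: float, molar_mass_g_mol: float) -> float:
    """Number of molecules in ``mass_g`` grams of a species of given molar mass."""
    if mass_g <= 0:
        raise ValueError("mass must be > 0")
    return mass_g / molar_mass_g_mol * AVOGADRO


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies) over a dilution series.

    ``points`` is an iterable of (copies, ct). Requires >= 3 points spanning
    at least two decades. Perfect doubling gives slope -1/log10(2) =
    -3.321928 and efficiency 1. A non-negative slope means the series did
    not amplify and is an error.
    """
    df = pd.DataFrame(points, columns=["copies", "ct"])
    if len(df) < 3:
        raise ValueError("need at least 3 dilution points")
    logc = np.log10(df["copies"].to_numpy(float))
    if logc.max() - logc.min() < 2.0:
        raise ValueError("dilution series must span at least 2 decades")
    res = stats.linregress(logc, df["ct"].to_numpy(float))
    if res.slope >= 0:
        raise ValueError("non-amplifying curve: slope >= 0")
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), points=df)


def copies_from_ct(curve: StandardCurve, ct) -> np.ndarray | float:
    """Interpolate absolute copies from Ct on a fitted standard curve."""
    return 10.0 ** ((np.asarray(ct, float) - curve.intercept) / curve.slope)


def copies_per_cell(copies_per_ug: float, pg_rna_per_cell: float = PG_RNA_PER_CELL) -> float:
    """Convert copies per µg of total RNA into copies per cell.

    copies/µg x pg/cell x 1e-6 µg/pg = copies/cell.
    """
    if copies_per_ug < 0 or pg_rna_per_cell <= 0:
        raise ValueError("inputs must be non-negative (pg_rna_per_cell > 0)")
    return copies_per_ug * pg_rna_per_cell * 1e-6


def exon_skip_abundance(total_copies: float, canonical_copies: float) -> tuple[float, str | None]:
    """Skipped-transcript copies: total minus canonical, clamped at zero.

    Measurement noise makes small negative differences expected; they are
    reported as 0 with a warning string rather than an error.
    """
    diff = total_copies - canonical_copies
    if diff < 0:
        return 0.0, (f"canonical ({canonical_copies}) exceeds total ({total_copies}); "
                     "clamped to 0")
    return diff, None


# ---------------------------------------------------------------------------
# gene copy number


def gcn_qpcr(
    ct: CtTable,
    target: str,
    centromeric_ref: str,
    parental_sample: str,
    amplified_threshold: float = 2.0,
    undetermined: str = "drop",
) -> pd.DataFrame:
    """qPCR gene copy number fold over a parental sample.

    dCt = Ct_target - Ct_centromere corrects for aneuploidy; the ddCt
    against the parental sample gives ``gcn_fold = 2^-ddCt``. A sample is
    flagged amplified when the fold reaches the (inclusive) twofold
    threshold.
    """
    mean = ct.mean_ct(undetermined)
    wide = mean.pivot(index="sample", columns="target", values="ct")
    for col in (target, centromeric_ref):
        if col not in wide.columns:
            raise ValueError(f"target {col!r} not in table")
    if parental_sample not in wide.index:
        raise ValueError(f"parental sample {parental_sample!r} not measured")
    dct = wide[target] - wide[centromeric_ref]
    if pd.isna(dct.loc[parental_sample]):
        raise ValueError("parental sample lacks target or centromeric Ct")
    fold = np.power(2.0, -(dct - dct.loc[parental_sample])).dropna()
    return pd.DataFrame(
        {"gcn_fold": fold, "amplified": fold >= amplified_threshold}
    )


# ---------------------------------------------------------------------------
# turnover and plasma


def decay_half_life(timepoints) -> tuple[float | None, list[str]]:
    """First-order decay half-life from (hours, fraction remaining) pairs.

    Fits ln(fraction) = a - k t by least squares; t1/2 = ln 2 / k. Points
    with fraction <= 0 are excluded and reported; a non-positive decay rate
    (flat or rising series) yields a missing half-life.
    """
    excluded = []
    t, y = [], []
    for hours, frac in timepoints:
        if frac <= 0:
            excluded.append(f"t={hours}: non-positive fraction {frac} excluded")
            continue
        if frac > 1.5:
            excluded.append(f"t={hours}: fraction {frac} > 1.5 excluded")
            continue
        t.append(float(hours))
        y.append(math.log(frac))
    if len(t) < 2:
        raise ValueError("need at least 2 usable timepoints")
    slope = stats.linregress(t, y).slope
    if slope >= 0:
        return None, excluded  # no measurable decay
    return math.log(2.0) / -slope, excluded


def plasma_copies_per_ml(
    dpcr_copies_per_ul_cdna: float, vc: VolumeChain | None = None
) -> float:
    """Convert a dPCR readout (copies/µl of input cDNA) to copies/ml plasma.

    Total cDNA copies = copies/µl x RT final volume; dividing by the
    fraction of the RNA eluate that entered the RT and by the plasma volume
    recovers the plasma concentration. With the default volume chain the
    multiplier is 20 / (15/100) / 1 = 133.33 per (copies/µl).
    """
    if vc is None:
        vc = VolumeChain()
    if dpcr_copies_per_ul_cdna < 0:
        raise ValueError("dPCR readout must be non-negative")
    return dpcr_copies_per_ul_cdna * vc.multiplier
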