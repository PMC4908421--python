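"""Glycan peak processing: normalization, derived traits, robustness QC, transforms.

An IgG N-glycome UPLC run integrates each chromatogram into 24 peaks
(GP1..GP24).  Downstream analysis works on *traits*: total-area-normalized
peak percentages, neutral-fraction percentages, and derived ratios that
summarize one structural feature (galactosylation, sialylation, core
fucosylation, bisecting GlcNAc) across peaks.

Technical quality is assessed with plate standards: biologically identical
aliquots run on every plate.  The robustness of a trait is the share of its
cohort variance attributable to experimental noise,

    robustness = 100 * Var(standards) / Var(cohort),

and only traits strictly below a robustness threshold (default 20%) are
carried into survival modelling.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

PEAKS: tuple[str, ...] = tuple(f"GP{i}" for i in range(1, 25))

#: metadata columns of a peak table (everything else must be GP1..GP24)
META_COLUMNS = ("sample_id", "plate_id", "is_standard")


class GlycomicsError(ValueError):
    """Raised for malformed peak tables, annotations or degenerate traits."""


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakAnnotation:
    """Structural annotation of the 24 chromatographic peaks.

    ``table`` is indexed by peak name with integer columns ``galactose``
    (0/1/2), ``sialic`` (0/1/2), flags ``fucose`` and ``bisecting``, and a
    ``reference_pct`` reference composition.  A peak is *neutral* iff its
    sialic-acid count is zero.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [p for p in PEAKS if p not in self.table.index]
        if missing or len(self.table) != len(PEAKS):
            raise GlycomicsError(
                f"annotation must cover GP1..GP24 exactly once; missing={missing}"
            )
        for col in ("galactose", "sialic", "fucose", "bisecting"):
            if col not in self.table.columns:
                raise GlycomicsError(f"annotation lacks column {col!r}")
        if not self.table["galactose"].isin([0, 1, 2]).all():
            raise GlycomicsError("galactose counts must be 0, 1 or 2")
        if not self.table["sialic"].isin([0, 1, 2]).all():
            raise GlycomicsError("sialic-acid counts must be 0, 1 or 2")

    @classmethod
    def from_tsv(cls, path) -> "PeakAnnotation":
        df = pd.read_csv(path, sep="\t", comment="#").set_index("peak")
        return cls(df.loc[list(PEAKS)])

    @classmethod
    def default(cls) -> "PeakAnnotation":
        ref = importlib.resources.files("glycoprog.data") / "peak_annotation.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @property
    def neutral(self) -> pd.Series:
        return self.table["sialic"] == 0

    @property
    def reference_profile(self) -> pd.Series:
        """Reference composition normalized to sum to 100."""
        ref = self.table["reference_pct"].astype(float)
        return 100.0 * ref / ref.sum()

    def peaks(
        self,
        *,
        galactose=None,
        min_galactose: int | None = None,
        sialic=None,
        min_sialic: int | None = None,
        fucose: bool | None = None,
        bisecting: bool | None = None,
        neutral: bool | None = None,
    ) -> tuple[str, ...]:
        """Peak names matching all given structural constraints."""
        mask = pd.Series(True, index=self.table.index)
        if galactose is not None:
            mask &= self.table["galactose"] == galactose
        if min_galactose is not None:
            mask &= self.table["galactose"] >= min_galactose
        if sialic is not None:
            mask &= self.table["sialic"] == sialic
        if min_sialic is not None:
            mask &= self.table["sialic"] >= min_sialic
        if fucose is not None:
            mask &= self.table["fucose"].astype(bool) == fucose
        if bisecting is not None:
            mask &= self.table["bisecting"].astype(bool) == bisecting
        if neutral is not None:
            mask &= self.neutral == neutral
        return tuple(self.table.index[mask])


# ---------------------------------------------------------------------------
# Trait definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitDefinition:
    """A trait as scale * sum(numerator peaks) / sum(denominator peaks)."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    scale: float = 100.0
    group: str = "derived"

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise GlycomicsError(f"trait {self.name}: empty peak set")
        if self.scale == 100.0 and not set(self.numerator) <= set(self.denominator):
            raise GlycomicsError(
                f"percentage trait {self.name}: numerator must be a denominator subset"
            )


def build_trait_definitions(annotation: PeakAnnotation) -> list[TraitDefinition]:
    """The packaged trait catalogue.

    24 directly measured peak percentages, one neutral percentage GPk^n per
    neutral peak, and 23 derived ratios covering galactosylation,
    sialylation, core fucosylation and bisecting GlcNAc.
    """
    a = annotation
    neutral = a.peaks(neutral=True)
    defs: list[TraitDefinition] = []

    for p in PEAKS:
        defs.append(TraitDefinition(p, (p,), PEAKS, 100.0, "measured"))
    for p in neutral:
        defs.append(TraitDefinition(f"{p}n", (p,), neutral, 100.0, "neutral"))

    def N(**kw):  # neutral subset selector
        return a.peaks(neutral=True, **kw)

    # galactosylation of the neutral fraction
    for g in (0, 1, 2):
        defs.append(TraitDefinition(f"G{g}n", N(galactose=g), neutral, 100.0))
    # core fucosylation / bisecting GlcNAc of the neutral fraction
    f_nb = N(fucose=True, bisecting=False)  # fucosylated, non-bisected
    f_b = N(fucose=True, bisecting=True)  # fucosylated, bisected
    b_any = N(bisecting=True)  # bisected (with or without fucose)
    f_all = N(fucose=True)
    defs.append(TraitDefinition("Fn", f_nb, neutral, 100.0))
    defs.append(TraitDefinition("FBn", f_b, neutral, 100.0))
    for g in (0, 1):
        defs.append(
            TraitDefinition(
                f"FG{g}n/G{g}n", N(fucose=True, bisecting=False, galactose=g),
                N(galactose=g), 100.0,
            )
        )
        defs.append(
            TraitDefinition(
                f"FBG{g}n/G{g}n", N(fucose=True, bisecting=True, galactose=g),
                N(galactose=g), 100.0,
            )
        )
    defs.append(TraitDefinition("FBn/Fn", f_b, f_nb, 1.0))
    defs.append(TraitDefinition("FBn/Fn total", f_b, f_all, 100.0))
    defs.append(TraitDefinition("Fn/(Bn+FBn)", f_nb, b_any, 1.0))

    # sialylation of fucosylated structures
    fgs = a.peaks(fucose=True, bisecting=False, min_sialic=1, min_galactose=1)
    fg = N(fucose=True, bisecting=False, min_galactose=1)
    fbgs = a.peaks(fucose=True, bisecting=True, min_sialic=1, min_galactose=1)
    fbg = N(fucose=True, bisecting=True, min_galactose=1)
    defs.append(TraitDefinition("FGS/(FG+FGS)", fgs, fg + fgs, 100.0))
    defs.append(TraitDefinition("FGS/(F+FG+FGS)", fgs, f_nb + fgs, 100.0))
    defs.append(TraitDefinition("FBGS/(FBG+FBGS)", fbgs, fbg + fbgs, 100.0))
    defs.append(TraitDefinition("FBGS/(FB+FBG+FBGS)", fbgs, f_b + fbgs, 100.0))
    fg2 = a.peaks(fucose=True, bisecting=False, galactose=2, sialic=0)
    fg2s1 = a.peaks(fucose=True, bisecting=False, galactose=2, sialic=1)
    fg2s2 = a.peaks(fucose=True, bisecting=False, galactose=2, sialic=2)
    fbg2 = a.peaks(fucose=True, bisecting=True, galactose=2, sialic=0)
    fbg2s1 = a.peaks(fucose=True, bisecting=True, galactose=2, sialic=1)
    fbg2s2 = a.peaks(fucose=True, bisecting=True, galactose=2, sialic=2)
    defs.append(
        TraitDefinition("FG2S1/(FG2+FG2S1+FG2S2)", fg2s1, fg2 + fg2s1 + fg2s2, 100.0)
    )
    defs.append(
        TraitDefinition(
            "FBG2S1/(FBG2+FBG2S1+FBG2S2)", fbg2s1, fbg2 + fbg2s1 + fbg2s2, 100.0
        )
    )

    # bisecting GlcNAc of sialylated structures
    fs1 = a.peaks(fucose=True, bisecting=False, sialic=1)
    fbs1 = a.peaks(fucose=True, bisecting=True, sialic=1)
    fs2 = a.peaks(fucose=True, bisecting=False, sialic=2)
    fbs2 = a.peaks(fucose=True, bisecting=True, sialic=2)
    defs.append(TraitDefinition("FBS total/FS total", fbs1 + fbs2, fs1 + fs2, 1.0))
    defs.append(TraitDefinition("FBS1/FS1", fbs1, fs1, 1.0))
    defs.append(TraitDefinition("FBS1/(FS1+FBS1)", fbs1, fs1 + fbs1, 1.0))
    defs.append(TraitDefinition("FBS2/FS2", fbs2, fs2, 1.0))
    defs.append(TraitDefinition("FBS2/(FS2+FBS2)", fbs2, fs2 + fbs2, 1.0))

    names = [d.name for d in defs]
    if len(names) != len(set(names)):
        raise GlycomicsError("duplicate trait names in catalogue")
    return defs


# ---------------------------------------------------------------------------
# Normalization and trait derivation
# ---------------------------------------------------------------------------


def _check_peak_table(table: pd.DataFrame) -> None:
    missing = [p for p in PEAKS if p not in table.columns]
    if missing:
        raise GlycomicsError(f"peak table missing columns: {missing}")
    areas = table[list(PEAKS)].to_numpy(float)
    if not np.isfinite(areas).all():
        raise GlycomicsError("peak areas must be finite")
    if (areas < 0).any():
        raise GlycomicsError("peak areas must be non-negative")


def normalize_total_area(table: pd.DataFrame) -> pd.DataFrame:
    """Total-area normalization: each row rescaled to sum to 100.

    Rows with zero total area are unanalysable; they are excluded with a
    logged warning.  Standard wells are normalized identically to cohort
    samples.
    """
    _check_peak_table(table)
    areas = table[list(PEAKS)].to_numpy(float)
    totals = areas.sum(axis=1)
    bad = totals <= 0
    if bad.any():
        logger.warning(
            "excluding %d zero-area row(s): %s",
            int(bad.sum()),
            list(table.loc[bad, "sample_id"]) if "sample_id" in table else "(no ids)",
        )
    out = table.loc[~bad].copy()
    out[list(PEAKS)] = 100.0 * areas[~bad] / totals[~bad, None]
    return out


def derive_traits(
    normalized: pd.DataFrame,
    definitions: list[TraitDefinition],
) -> pd.DataFrame:
    """Compute every trait for every row of a normalized peak table.

    A sample with a zero denominator for some trait gets a missing value for
    that trait (logged).  Metadata columns of the input are carried through.
    """
    meta = [c for c in META_COLUMNS if c in normalized.columns]
    out = normalized[meta].copy()
    areas = normalized[list(PEAKS)]
    for d in definitions:
        num = areas[list(d.numerator)].sum(axis=1)
        den = areas[list(d.denominator)].sum(axis=1)
        zero = den <= 0
        if zero.any():
            logger.warning(
                "trait %s: zero denominator for %d sample(s); set missing",
                d.name, int(zero.sum()),
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = d.scale * num / den
        out[d.name] = vals.where(~zero)
    return out


# ---------------------------------------------------------------------------
# Robustness QC
# ---------------------------------------------------------------------------


def robustness(
    standard_values: pd.DataFrame, cohort_values: pd.DataFrame
) -> pd.Series:
    """Experimental-variance share per trait.

    100 * Var(standard wells) / Var(cohort samples), unbiased sample
    variances, standards pooled across plates.  Traits with zero cohort
    variance are undefined (NaN) and reported as not retainable.
    """
    traits = [c for c in cohort_values.columns if c not in META_COLUMNS]
    out = {}
    for t in traits:
        s = standard_values[t].dropna()
        c = cohort_values[t].dropna()
        if len(s) < 2 or len(c) < 2:
            raise GlycomicsError(
                f"robustness of {t}: need >=2 standards and >=2 cohort values"
            )
        var_c = c.var(ddof=1)
        if var_c == 0:
            logger.warning("trait %s: zero cohort variance; robustness undefined", t)
            out[t] = np.nan
        else:
            out[t] = 100.0 * s.var(ddof=1) / var_c
    return pd.Series(out, name="robustness")


@dataclass
class TraitMatrix:
    """Per-sample trait values with QC annotations.

    ``values`` holds one row per cohort sample (metadata + one column per
    trait); ``robustness`` and ``retained`` are per-trait.
    """

    values: pd.DataFrame
    robustness: pd.Series
    retained: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.values.columns if c not in META_COLUMNS]

    @property
    def retained_names(self) -> list[str]:
        if self.retained is None:
            return self.trait_names
        return [t for t in self.trait_names if bool(self.retained.get(t, False))]


def filter_robust(matrix: TraitMatrix, threshold: float = 20.0) -> TraitMatrix:
    """Retain traits whose robustness is strictly below ``threshold``.

    Boundary values (robustness == threshold) and undefined robustness are
    excluded — the comparison is strict.
    """
    rob = matrix.robustness
    retained = pd.Series(
        {t: bool(np.isfinite(rob.get(t, np.nan)) and rob[t] < threshold)
         for t in matrix.trait_names}
    )
    logger.info(
        "robustness filter at %.4g%%: %d of %d traits retained",
        threshold, int(retained.sum()), len(retained),
    )
    return TraitMatrix(matrix.values, rob, retained)


def qc_trait_matrix(
    peak_table: pd.DataFrame,
    annotation: PeakAnnotation | None = None,
    definitions: list[TraitDefinition] | None = None,
    threshold: float = 20.0,
) -> TraitMatrix:
    """Full glycomics stage: normalize, derive, robustness-score and filter."""
    annotation = annotation or PeakAnnotation.default()
    definitions = definitions or build_trait_definitions(annotation)
    norm = normalize_total_area(peak_table)
    traits = derive_traits(norm, definitions)
    is_std = traits["is_standard"].astype(bool)
    rob = robustness(traits[is_std], traits[~is_std])
    return filter_robust(TraitMatrix(traits[~is_std].copy(), rob), threshold)


# ---------------------------------------------------------------------------
# Rank-normal transform
# ---------------------------------------------------------------------------


def rank_normal_transform(values) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    Replaces each value by the standard-normal quantile of its Blom-adjusted
    rank, (rank - 3/8) / (n + 1/4), with average ranks for ties.  Missing
    values stay missing; all-identical input is degenerate and rejected.
    """
    x = np.asarray(values, float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 2:
        raise GlycomicsError("rank-normal transform needs >=2 non-missing values")
    xv = x[ok]
    if np.all(xv == xv[0]):
        raise GlycomicsError("rank-normal transform of a constant trait")
    ranks = rankdata(xv, method="average")
    out[ok] = ndtri((ranks - 0.375) / (n + 0.25))
    return out
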