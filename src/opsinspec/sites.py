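"""Comparative spectral tuning-site analysis of aligned opsins.

Workflow: read a pre-computed amino-acid alignment, map alignment columns to
reference-sequence numbering (e.g. mouse melanopsin Opn4L positions), extract
the residues every species carries at a set of binding-pocket sites, classify
substitutions with the OH-rule, group species with identical residue
profiles, and summarise a λmax table.

The OH-rule heuristic: gaining a hydroxyl-bearing residue (Ser/Thr/Tyr) near
the β-ionone ring of retinal red-shifts λmax, gaining one near the retinal
Schiff base (RSB) blue-shifts it, and losses reverse the sign.  Sites nearly
equidistant from both moieties are treated as unpredictable ("no expected
change").

Packaged reference tables (transcribed measurement summaries for 22
mammalian melanopsins and the 8 non-conserved pocket sites, with modelled
distances to the chromophore) back the comparative screen without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "DEFAULT_SITES",
    "OH_RESIDUES",
    "AlignedOpsinSet",
    "ShiftPrediction",
    "ProfileGroups",
    "LambdaTableStats",
    "load_lambda_max_table",
    "load_site_geometry",
    "load_site_residues",
    "site_matrix_from_long",
    "map_numbering",
    "extract_site_matrix",
    "classify_oh_substitution",
    "predict_site_shifts",
    "identical_profile_groups",
    "lambda_table_stats",
]

DEFAULT_SITES = (152, 155, 158, 197, 302, 310, 311, 329)
OH_RESIDUES = frozenset({"S", "T", "Y"})

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_GAP = "-"


# ---------------------------------------------------------------------------
# packaged tables
# ---------------------------------------------------------------------------

def _packaged(name: str) -> pd.DataFrame:
    with resources.files("opsinspec.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_lambda_max_table(path=None) -> pd.DataFrame:
    """λmax ± SE per species (packaged 22-species table by default)."""
    df = pd.read_csv(path) if path is not None else _packaged(
        "melanopsin_lambda_max.csv")
    required = {"species", "lambda_max_nm"}
    if not required <= set(df.columns):
        raise ValueError(f"λmax table needs columns {sorted(required)}")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in λmax table")
    lm = df["lambda_max_nm"]
    if ((lm < 350) | (lm > 600)).any():
        raise ValueError("λmax values must lie within 350-600 nm")
    return df


def load_site_geometry(path=None) -> pd.DataFrame:
    """Per-site distances (Å) to the RSB nitrogen and β-ionone ring."""
    df = pd.read_csv(path) if path is not None else _packaged(
        "melanopsin_site_geometry.csv")
    required = {"site", "d_rsb_angstrom", "d_beta_angstrom"}
    if not required <= set(df.columns):
        raise ValueError(f"site geometry needs columns {sorted(required)}")
    if ((df["d_rsb_angstrom"] <= 0) | (df["d_beta_angstrom"] <= 0)).any():
        raise ValueError("distances must be positive")
    return df.set_index("site", drop=False)


def load_site_residues(path=None) -> pd.DataFrame:
    """Long-format per-species residues at the pocket sites.

    Columns: species, site, residue, expected_shift (blank where no shift
    annotation applies).
    """
    df = pd.read_csv(
        path if path is not None
        else resources.files("opsinspec.data") / "melanopsin_site_residues.csv",
        keep_default_na=False,
    )
    required = {"species", "site", "residue"}
    if not required <= set(df.columns):
        raise ValueError(f"site residues need columns {sorted(required)}")
    return df


def site_matrix_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format residues to a species × site matrix."""
    return long.pivot(index="species", columns="site", values="residue")


# ---------------------------------------------------------------------------
# alignment handling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedOpsinSet:
    """Pre-aligned amino-acid sequences keyed by species/sequence id."""

    sequences: dict[str, str]
    reference_id: str

    def __post_init__(self) -> None:
        if self.reference_id not in self.sequences:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must share one length")
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - _AA - {_GAP}
            if bad:
                raise ValueError(
                    f"{name}: non-standard residue(s) {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, path, reference_id: str) -> "AlignedOpsinSet":
        aln = AlignIO.read(path, "fasta")
        return cls({rec.id: str(rec.seq).upper() for rec in aln}, reference_id)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


def map_numbering(alignment: AlignedOpsinSet,
                  reference_id: str | None = None) -> dict[int, int]:
    """Map 1-based reference positions to 0-based alignment columns.

    Gap columns of the reference carry no position; the map is a bijection
    between ungapped reference positions and their columns.
    """
    ref_id = reference_id or alignment.reference_id
    if ref_id not in alignment.sequences:
        raise ValueError(f"reference id {ref_id!r} not in alignment")
    ref = alignment.sequences[ref_id]
    mapping: dict[int, int] = {}
    pos = 0
    for col, residue in enumerate(ref):
        if residue != _GAP:
            pos += 1
            mapping[pos] = col
    return mapping


def extract_site_matrix(
    alignment: AlignedOpsinSet,
    sites=DEFAULT_SITES,
    reference_id: str | None = None,
) -> pd.DataFrame:
    """Residues of every species at the given reference-numbered sites."""
    mapping = map_numbering(alignment, reference_id)
    cols = {}
    for site in sites:
        if site not in mapping:
            raise ValueError(
                f"site {site} is outside the ungapped reference (length "
                f"{max(mapping)})"
            )
        cols[site] = mapping[site]
    data = {
        name: [seq[cols[site]] for site in sites]
        for name, seq in alignment.sequences.items()
    }
    out = pd.DataFrame.from_dict(data, orient="index", columns=list(sites))
    out.index.name = "species"
    out.columns.name = "site"
    return out


# ---------------------------------------------------------------------------
# OH-rule classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftPrediction:
    """OH-rule verdict for one substitution at one pocket site."""

    site: int
    substitution: str  # e.g. "A197S"
    prediction: str  # "red" | "blue" | "none"
    rationale: str


def classify_oh_substitution(
    ref_res: str,
    var_res: str,
    d_beta: float,
    d_rsb: float,
    ambiguity_margin: float = 1.0,
    site: int = 0,
) -> ShiftPrediction:
    """Classify a substitution's expected λmax shift by the OH-rule.

    Gain of an OH-bearing residue (S/T/Y) nearer the β-ionone ring than the
    RSB predicts a red-shift; nearer the RSB, a blue-shift; loss reverses
    the sign.  Substitutions that leave OH status unchanged, and sites
    whose two distances differ by less than ``ambiguity_margin`` Å, predict
    no change.
    """
    ref_res, var_res = ref_res.upper(), var_res.upper()
    for r in (ref_res, var_res):
        if r not in _AA:
            raise ValueError(f"non-standard residue: {r!r}")
    if d_beta <= 0 or d_rsb <= 0:
        raise ValueError("distances must be positive")
    sub = f"{ref_res}{site}{var_res}" if site else f"{ref_res}->{var_res}"
    ref_oh, var_oh = ref_res in OH_RESIDUES, var_res in OH_RESIDUES
    if ref_oh == var_oh:
        return ShiftPrediction(site, sub, "none",
                               "OH status unchanged by substitution")
    if abs(d_beta - d_rsb) < ambiguity_margin:
        return ShiftPrediction(
            site, sub, "none",
            f"site nearly equidistant from β-ionone ({d_beta} Å) and RSB "
            f"({d_rsb} Å)",
        )
    near_beta = d_beta < d_rsb
    gain = var_oh  # True: gained OH group; False: lost it
    if gain == near_beta:
        prediction = "red"
    else:
        prediction = "blue"
    moiety = "β-ionone ring" if near_beta else "Schiff base"
    change = "gain" if gain else "loss"
    return ShiftPrediction(site, sub, prediction,
                           f"{change} of OH group nearer the {moiety}")


def predict_site_shifts(
    site_matrix: pd.DataFrame,
    geometry: pd.DataFrame | None = None,
    reference_species: str = "mouse",
    ambiguity_margin: float = 1.0,
) -> pd.DataFrame:
    """OH-rule predictions for every species × site deviation from reference.

    Returns rows (species, site, substitution, prediction, rationale) for
    each residue differing from the reference species (gaps skipped).
    """
    if geometry is None:
        geometry = load_site_geometry()
    if reference_species not in site_matrix.index:
        raise ValueError(f"reference species {reference_species!r} not in matrix")
    ref_row = site_matrix.loc[reference_species]
    rows = []
    for species, row in site_matrix.iterrows():
        if species == reference_species:
            continue
        for site in site_matrix.columns:
            ref_res, var_res = ref_row[site], row[site]
            if var_res in (_GAP, ref_res):
                continue
            geo = geometry.loc[site]
            pred = classify_oh_substitution(
                ref_res, var_res,
                d_beta=float(geo["d_beta_angstrom"]),
                d_rsb=float(geo["d_rsb_angstrom"]),
                ambiguity_margin=ambiguity_margin,
                site=int(site),
            )
            rows.append((species, int(site), pred.substitution,
                         pred.prediction, pred.rationale))
    return pd.DataFrame(
        rows, columns=["species", "site", "substitution", "prediction",
                       "rationale"]
    )


# ---------------------------------------------------------------------------
# profile grouping and λmax statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileGroups:
    """Species grouped by identical residue profiles across the sites."""

    groups: pd.DataFrame  # profile, species list, n, min/max λmax, range
    max_range_nm: float
    max_range_profile: str


def identical_profile_groups(
    site_matrix: pd.DataFrame,
    lmax_table: pd.DataFrame,
) -> ProfileGroups:
    """Group species by identical residue strings; report λmax divergence.

    Order of species and of sites does not affect the result (sites are
    sorted before profiles are formed).
    """
    lmax = lmax_table.set_index("species")["lambda_max_nm"]
    shared = [s for s in site_matrix.index if s in lmax.index]
    if not shared:
        raise ValueError("no species shared between site matrix and λmax table")
    ordered_sites = sorted(site_matrix.columns)
    profiles = site_matrix.loc[shared, ordered_sites].agg("".join, axis=1)
    rows = []
    for profile, members in sorted(profiles.groupby(profiles).groups.items()):
        members = sorted(members)
        vals = lmax.loc[members]
        rows.append((
            profile, ",".join(members), len(members),
            float(vals.min()), float(vals.max()),
            float(vals.max() - vals.min()),
        ))
    groups = pd.DataFrame(
        rows, columns=["profile", "species", "n", "lambda_max_min",
                       "lambda_max_max", "range_nm"]
    ).sort_values("range_nm", ascending=False).reset_index(drop=True)
    top = groups.iloc[0]
    return ProfileGroups(
        groups=groups,
        max_range_nm=float(top["range_nm"]),
        max_range_profile=str(top["profile"]),
    )


@dataclass(frozen=True)
class LambdaTableStats:
    """Summary statistics of a species λmax table."""

    mean_nm: float
    min_nm: float
    max_nm: float
    range_nm: float
    n_species: int
    reference_species: str
    shifts_nm: pd.Series  # per-species λmax − reference λmax

    @property
    def mean_reported(self) -> float:
        """Mean rounded to 1 decimal, the table-reporting convention."""
        return round(self.mean_nm, 1)


def lambda_table_stats(
    lmax_table: pd.DataFrame,
    reference_species: str = "mouse",
) -> LambdaTableStats:
    """Mean/min/max/range of λmax point estimates and shifts vs reference.

    SEs are ignored; the mean is the plain arithmetic mean of the point
    estimates.
    """
    if len(lmax_table) < 1:
        raise ValueError("λmax table is empty")
    lmax = lmax_table.set_index("species")["lambda_max_nm"].astype(float)
    if reference_species not in lmax.index:
        raise ValueError(f"unknown reference species {reference_species!r}")
    return LambdaTableStats(
        mean_nm=float(lmax.mean()),
        min_nm=float(lmax.min()),
        max_nm=float(lmax.max()),
        range_nm=float(lmax.max() - lmax.min()),
        n_species=len(lmax),
        reference_species=reference_species,
        shifts_nm=lmax - lmax[reference_species],
    )
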