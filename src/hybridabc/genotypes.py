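"""Dosage-matrix data model and filtering cascade for DArT-style SNP tables.

A dataset couples a diploid dosage matrix (counts of the alternate allele,
0/1/2, with a single missing-data sentinel) with per-locus metadata
(reproducibility, clone grouping of secondary SNPs) and per-individual group
labels.  The filter functions reproduce the standard genotyping-by-sequencing
quality cascade: locus reproducibility, locus call rate, individual call
rate, monomorphic-locus removal, one-SNP-per-clone thinning, within-group
polymorphism, and pooled minor-allele-frequency thresholds.  Call rates are
always recomputed on the current (already filtered) matrix, so the order in
which filters are applied matters.

Dosages count the alternate allele as given by the input file; alleles are
never re-polarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call in the dosage matrix.
MISSING: int = -1

#: Tokens read as missing data in DArT-style CSV files.
_MISSING_TOKENS = {"NA", "-", "", "NaN", "nan"}

LOCUS_COLUMNS = ["locus_id", "clone_id", "reproducibility", "allele_ref", "allele_alt"]


class DartFormatError(ValueError):
    """Malformed DArT-style CSV input (bad header or invalid dosage)."""


@dataclass
class SnpDataset:
    """Biallelic diploid SNP dataset.

    Parameters
    ----------
    individuals
        DataFrame with columns ``individual_id`` (unique) and ``group_label``.
    loci
        DataFrame with columns ``locus_id`` (unique), ``clone_id`` (non-empty),
        ``reproducibility`` (fraction in [0, 1]), ``allele_ref``, ``allele_alt``.
    dosages
        ``int8`` matrix of shape (n individuals, n loci); entries in
        ``{0, 1, 2, MISSING}``.
    """

    individuals: pd.DataFrame
    loci: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if not self.individuals["individual_id"].is_unique:
            raise ValueError("individual_id values must be unique")
        if not self.loci["locus_id"].is_unique:
            raise ValueError("locus_id values must be unique")
        if (self.loci["clone_id"].astype(str) == "").any():
            raise ValueError("clone_id must be non-empty")
        rep = self.loci["reproducibility"].to_numpy(dtype=float)
        if ((rep < 0) | (rep > 1)).any():
            raise ValueError("reproducibility must lie in [0, 1]")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[i, j]} at individual "
                f"{self.individuals['individual_id'][i]!r}, locus {self.loci['locus_id'][j]!r}"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def group_indices(self) -> dict[str, np.ndarray]:
        """Map group label -> row indices of its individuals (input order)."""
        out: dict[str, np.ndarray] = {}
        labels = self.individuals["group_label"].to_numpy()
        for g in pd.unique(labels):
            out[g] = np.flatnonzero(labels == g)
        return out

    def take_loci(self, index: np.ndarray) -> "SnpDataset":
        """Subset loci (columns), preserving individual order."""
        index = np.asarray(index)
        return SnpDataset(self.individuals.copy(), self.loci.iloc[index], self.dosages[:, index])

    def take_individuals(self, index: np.ndarray) -> "SnpDataset":
        """Subset individuals (rows), preserving locus order."""
        index = np.asarray(index)
        return SnpDataset(self.individuals.iloc[index], self.loci.copy(), self.dosages[index, :])

    def with_groups(self, group_map: pd.DataFrame | dict) -> "SnpDataset":
        """Return a copy with ``group_label`` taken from a two-column table.

        ``group_map`` is either a mapping ``individual_id -> group_label`` or a
        DataFrame with columns ``individual_id`` and ``group_label``.
        """
        if isinstance(group_map, pd.DataFrame):
            mapping = dict(zip(group_map["individual_id"], group_map["group_label"]))
        else:
            mapping = dict(group_map)
        ind = self.individuals.copy()
        missing = [i for i in ind["individual_id"] if i not in mapping]
        if missing:
            raise ValueError(f"no group label for individuals: {missing[:5]}")
        ind["group_label"] = [mapping[i] for i in ind["individual_id"]]
        return SnpDataset(ind, self.loci.copy(), self.dosages.copy())

    # -- per-locus/individual summaries ---------------------------------

    def locus_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per locus over current individuals."""
        if self.n_individuals == 0:
            return np.ones(self.n_loci)
        return (self.dosages != MISSING).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per individual over current loci."""
        if self.n_loci == 0:
            return np.ones(self.n_individuals)
        return (self.dosages != MISSING).mean(axis=1)

    def alt_allele_frequency(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Pooled alternate-allele frequency per locus (NaN where all missing)."""
        d = self.dosages if rows is None else self.dosages[rows]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0, dtype=float)
        n_copies = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_copies > 0, alt / n_copies, np.nan)


# ---------------------------------------------------------------------------
# I/O: DArT-style CSV dialect
# ---------------------------------------------------------------------------


def read_dart_csv(path, group_map: pd.DataFrame | dict | None = None) -> SnpDataset:
    """Read a DArT-style CSV (one locus per row) into a :class:`SnpDataset`.

    The header must start with ``locus_id, clone_id, reproducibility,
    allele_ref, allele_alt`` followed by one column per individual.  Dosages
    are ``0/1/2``; missing calls are ``NA`` or ``-``.  Any other non-numeric
    call symbol is mapped to missing with a logged count; a numeric dosage
    outside {0, 1, 2} raises :class:`DartFormatError` naming the cell.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    header = list(df.columns)
    for k, expected in enumerate(LOCUS_COLUMNS):
        if k >= len(header) or header[k] != expected:
            got = header[k] if k < len(header) else "<absent>"
            raise DartFormatError(
                f"malformed header: expected column {k} to be {expected!r}, got {got!r}"
            )
    ind_ids = header[len(LOCUS_COLUMNS):]
    if not ind_ids:
        raise DartFormatError("malformed header: no individual columns found")

    loci = df[LOCUS_COLUMNS].copy()
    loci["reproducibility"] = loci["reproducibility"].astype(float)

    calls = df[ind_ids].to_numpy().T  # individuals x loci, strings
    dosages = np.empty(calls.shape, dtype=np.int8)
    unknown = 0
    for (i, j), tok in np.ndenumerate(calls):
        tok = tok.strip()
        if tok in _MISSING_TOKENS:
            dosages[i, j] = MISSING
        else:
            try:
                v = int(float(tok))
            except ValueError:
                dosages[i, j] = MISSING
                unknown += 1
                continue
            if v not in (0, 1, 2):
                raise DartFormatError(
                    f"dosage {tok!r} outside {{0,1,2,NA}} at row {j + 2}, column {ind_ids[i]!r}"
                )
            dosages[i, j] = v
    if unknown:
        logger.warning("mapped %d unknown call symbols to missing", unknown)

    individuals = pd.DataFrame({"individual_id": ind_ids, "group_label": ""})
    ds = SnpDataset(individuals, loci, dosages)
    if group_map is not None:
        ds = ds.with_groups(group_map)
    return ds


def write_dart_csv(ds: SnpDataset, path, missing_code: str = "NA") -> None:
    """Write the identical CSV dialect read by :func:`read_dart_csv`."""
    out = ds.loci[LOCUS_COLUMNS].copy()
    for i, ind in enumerate(ds.individuals["individual_id"]):
        col = ds.dosages[i].astype(object)
        col[ds.dosages[i] == MISSING] = missing_code
        out[ind] = col
    out.to_csv(path, index=False)


def read_group_table(path) -> pd.DataFrame:
    """Read a two-column ``individual_id, group_label`` table (CSV)."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["individual_id", "group_label"]:
        raise DartFormatError("group table must have columns individual_id, group_label")
    return df


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------


def filter_loci(
    ds: SnpDataset, min_reproducibility: float, min_locus_call_rate: float
) -> SnpDataset:
    """Keep loci with reproducibility and call rate at or above the thresholds."""
    for name, v in (("min_reproducibility", min_reproducibility),
                    ("min_locus_call_rate", min_locus_call_rate)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rep = ds.loci["reproducibility"].to_numpy(dtype=float)
    keep = (rep >= min_reproducibility) & (ds.locus_call_rate() >= min_locus_call_rate)
    if not keep.any():
        logger.warning("filter_loci removed every locus")
    return ds.take_loci(np.flatnonzero(keep))


def filter_individuals(ds: SnpDataset, min_individual_call_rate: float) -> SnpDataset:
    """Keep individuals whose call rate over current loci meets the threshold."""
    if not 0 <= min_individual_call_rate <= 1:
        raise ValueError("min_individual_call_rate must lie in [0, 1]")
    keep = ds.individual_call_rate() >= min_individual_call_rate
    if not keep.any():
        logger.warning("filter_individuals removed every individual")
    return ds.take_individuals(np.flatnonzero(keep))


def _polymorphic_mask(ds: SnpDataset, rows: np.ndarray | None = None) -> np.ndarray:
    """True where the alt-allele frequency is strictly between 0 and 1."""
    p = ds.alt_allele_frequency(rows)
    with np.errstate(invalid="ignore"):
        return (p > 0) & (p < 1)


def remove_monomorphic(ds: SnpDataset) -> SnpDataset:
    """Drop loci where only one allele segregates among non-missing calls."""
    return ds.take_loci(np.flatnonzero(_polymorphic_mask(ds)))


def thin_secondary_snps(ds: SnpDataset, rng_seed: int) -> SnpDataset:
    """Keep one uniformly chosen SNP per clone (sequenced fragment).

    Deterministic for a fixed seed; output loci keep their original order.
    """
    rng = np.random.default_rng(rng_seed)
    clones = ds.loci["clone_id"].to_numpy()
    keep = []
    for clone in pd.unique(clones):
        members = np.flatnonzero(clones == clone)
        keep.append(members[rng.integers(len(members))])
    keep = np.sort(np.asarray(keep, dtype=int))
    return ds.take_loci(keep)


def filter_group_polymorphism(
    ds: SnpDataset, groups: list[str], mode: str = "strict"
) -> SnpDataset:
    """Keep loci by within-group polymorphism over the named groups.

    ``mode="strict"`` (default) retains a locus only if it segregates within
    *every* named group.  ``mode="weak"`` drops a locus only when it is
    monomorphic in *all* named groups simultaneously.
    """
    if mode not in ("strict", "weak"):
        raise ValueError("mode must be 'strict' or 'weak'")
    idx = ds.group_indices()
    for g in groups:
        if g not in idx or len(idx[g]) == 0:
            raise ValueError(f"group {g!r} has no individuals")
    masks = np.vstack([_polymorphic_mask(ds, idx[g]) for g in groups])
    keep = masks.all(axis=0) if mode == "strict" else masks.any(axis=0)
    return ds.take_loci(np.flatnonzero(keep))


def filter_maf(ds: SnpDataset, min_maf: float) -> SnpDataset:
    """Keep loci with pooled minor-allele frequency >= ``min_maf`` (inclusive)."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    p = ds.alt_allele_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1 - p)
    keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= min_maf)
    return ds.take_loci(keep)
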