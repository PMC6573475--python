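"""Domain types and readers/writers for haploid haplotype data.

The central object is :class:`HaplotypeAlignment`: per-sample state vectors
over the polymorphic sites of a single non-recombining haploid locus (such as
the male-specific region of the Y chromosome), together with population
assignments and the total surveyed length in bp.  Alignments can be read from
FASTA (headers ``sampleID|populationCode``) or from a TSV site table, and are
the common input of every downstream statistic.

Monomorphic positions are never stored: an alignment holds only polymorphic
columns plus ``locus_length_bp``, which matters only for per-bp rates, never
for the statistics computed here.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = "N"

LANGUAGE_FAMILIES = ("AA", "TK", "ST", "HM", "other")
RESIDENCE_CLASSES = ("patrilocal", "matrilocal", "neutral", "unknown")


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate ids, bad ranges...)."""


class FormatError(ValueError):
    """File content is malformed (ragged sequences, missing columns...)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but too small/empty for the operation."""


@dataclass
class HaplotypeAlignment:
    """Aligned state vectors over polymorphic sites of one haploid locus.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per row of ``sites``.
    populations : sequence of str
        Population code per sample, parallel to ``sample_ids``.
    sites : ndarray of shape (n_samples, n_sites), dtype ``<U1``
        Per-sample states; ``"N"`` marks missing data.  States are
        nucleotides, or ``"0"``/``"1"`` for polarized ancestral/derived data.
    locus_length_bp : int
        Total surveyed length; must be >= the number of stored site columns.
    ancestral_states : ndarray of shape (n_sites,), optional
        Ancestral allele per site; required to compute an unfolded SFS.
    """

    sample_ids: list[str]
    populations: list[str]
    sites: np.ndarray
    locus_length_bp: int
    ancestral_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.populations = list(self.populations)
        self.sites = np.asarray(self.sites, dtype="<U1")
        if self.sites.ndim != 2:
            raise FormatError("site matrix must be 2-dimensional")
        if len(self.sample_ids) != self.sites.shape[0]:
            raise ValidationError("sample_ids length does not match site matrix")
        if len(self.populations) != len(self.sample_ids):
            raise ValidationError("populations length does not match sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample id")
        if self.locus_length_bp < self.sites.shape[1]:
            raise ValidationError(
                f"locus_length_bp={self.locus_length_bp} smaller than number "
                f"of site columns ({self.sites.shape[1]})"
            )
        if self.ancestral_states is not None:
            self.ancestral_states = np.asarray(self.ancestral_states, dtype="<U1")
            if self.ancestral_states.shape != (self.sites.shape[1],):
                raise ValidationError("ancestral_states length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return int(self.sites.shape[1])

    @property
    def population_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.populations))

    def population_codes(self) -> list[str]:
        """Distinct population codes in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def subset(self, sample_indices: Sequence[int]) -> "HaplotypeAlignment":
        idx = np.asarray(sample_indices, dtype=int)
        return HaplotypeAlignment(
            sample_ids=[self.sample_ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            sites=self.sites[idx],
            locus_length_bp=self.locus_length_bp,
            ancestral_states=self.ancestral_states,
        )

    def restrict_to_population(self, code: str) -> "HaplotypeAlignment":
        idx = [i for i, p in enumerate(self.populations) if p == code]
        return self.subset(idx)


@dataclass
class PopulationMetadata:
    """Per-population annotations: ethnolinguistic group, location, residence."""

    code: str
    ethnicity: str
    language_family: str
    region: str
    latitude: float
    longitude: float
    residence: str
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude out of range: {self.longitude}")
        if self.language_family not in LANGUAGE_FAMILIES:
            self.language_family = "other"
        if self.residence not in RESIDENCE_CLASSES:
            warnings.warn(
                f"unknown residence value {self.residence!r} for population "
                f"{self.code}; mapped to 'unknown'",
                stacklevel=2,
            )
            self.residence = "unknown"
        if self.n_samples < 0:
            raise ValidationError("n_samples must be >= 0")


@dataclass
class HaplotypeTable:
    """Distinct haplotypes and their per-population counts.

    ``counts`` is a populations x haplotypes integer matrix; row sums equal
    population sample sizes.
    """

    haplotypes: dict[str, str]  # haplotype_id -> joined state string
    counts: pd.DataFrame  # index = population codes, columns = haplotype ids

    def __post_init__(self) -> None:
        if len(set(self.haplotypes.values())) != len(self.haplotypes):
            raise ValidationError("haplotype state vectors are not distinct")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative haplotype count")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def population_counts(self, code: str) -> np.ndarray:
        """Nonzero haplotype counts for one population."""
        row = self.counts.loc[code].to_numpy()
        return row[row > 0]


MATRIX_KINDS = ("phist", "dA", "geographic", "pairwise_diff", "similarity")


@dataclass
class DistanceMatrix:
    """Labelled square matrix of pairwise values.

    Phi-st entries may be negative; no metric property is assumed or checked
    beyond symmetry and a zero diagonal.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "pairwise_diff"

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if n and not np.allclose(
            self.values, self.values.T, atol=1e-12, rtol=0, equal_nan=True
        ):
            raise ValidationError("matrix not symmetric within 1e-12")
        if n and not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal not zero")
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries, row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Readers


def _validate_and_build(
    sample_ids: list[str],
    populations: list[str],
    rows: list[str] | list[list[str]],
    locus_length_bp: int,
) -> HaplotypeAlignment:
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise FormatError(f"ragged sequence lengths: {sorted(lengths)}")
    n_sites = lengths.pop() if lengths else 0
    mat = np.full((len(rows), n_sites), MISSING, dtype="<U1")
    for i, r in enumerate(rows):
        mat[i] = list(r)
    return HaplotypeAlignment(sample_ids, populations, mat, locus_length_bp)


def read_alignment(
    path: str | Path, format: str = "fasta", locus_length_bp: int | None = None
) -> HaplotypeAlignment:
    """Read a haplotype alignment from FASTA or a TSV site table.

    FASTA headers must be ``sampleID|populationCode``.  Site tables have
    columns ``sample_id``, ``population``, then one column per polymorphic
    site; empty cells become missing (``N``).

    Reading is pure: the same file bytes always yield an identical object.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        sample_ids, populations, rows = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.id
            if "|" not in header:
                raise FormatError(
                    f"FASTA header {header!r} lacks 'sampleID|populationCode'"
                )
            sid, pop = header.split("|", 1)
            sample_ids.append(sid)
            populations.append(pop)
            rows.append(str(rec.seq).upper())
        if locus_length_bp is None:
            locus_length_bp = len(rows[0]) if rows else 0
        return _validate_and_build(sample_ids, populations, rows, locus_length_bp)
    if format == "site_table":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = ["sample_id", "population"]
        if list(df.columns[:2]) != required:
            raise FormatError(
                "site table must start with columns sample_id, population"
            )
        site_cols = list(df.columns[2:])
        sample_ids = df["sample_id"].tolist()
        populations = df["population"].tolist()
        rows = []
        for _, rec in df.iterrows():
            rows.append(
                [
                    (str(rec[c]).upper() if str(rec[c]).strip() else MISSING)
                    for c in site_cols
                ]
            )
        if locus_length_bp is None:
            locus_length_bp = len(site_cols)
        return _validate_and_build(sample_ids, populations, rows, locus_length_bp)
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment(alignment: HaplotypeAlignment, path: str | Path) -> None:
    """Write an alignment as FASTA with ``sampleID|populationCode`` headers."""
    records = [
        SeqRecord(
            Seq("".join(alignment.sites[i])),
            id=f"{sid}|{pop}",
            description="",
        )
        for i, (sid, pop) in enumerate(
            zip(alignment.sample_ids, alignment.populations)
        )
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path: str | Path) -> list[PopulationMetadata]:
    """Read per-population metadata from TSV.

    Expected header: ``code ethnicity language_family region latitude
    longitude residence``.  Unknown residence values map to ``unknown`` with
    a warning; out-of-range coordinates or duplicate codes raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = [
        "code",
        "ethnicity",
        "language_family",
        "region",
        "latitude",
        "longitude",
        "residence",
    ]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    if df["code"].duplicated().any():
        dupes = df.loc[df["code"].duplicated(), "code"].tolist()
        raise ValidationError(f"duplicate population codes: {dupes}")
    out = []
    for _, row in df.iterrows():
        out.append(
            PopulationMetadata(
                code=row["code"],
                ethnicity=row["ethnicity"],
                language_family=row["language_family"],
                region=row["region"],
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                residence=row["residence"],
                n_samples=int(row["n_samples"]) if "n_samples" in df.columns else 0,
            )
        )
    return out


def write_metadata(metadata: Iterable[PopulationMetadata], path: str | Path) -> None:
    rows = [
        {
            "code": m.code,
            "ethnicity": m.ethnicity,
            "language_family": m.language_family,
            "region": m.region,
            "latitude": m.latitude,
            "longitude": m.longitude,
            "residence": m.residence,
            "n_samples": m.n_samples,
        }
        for m in metadata
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Core transformations


def complete_deletion(alignment: HaplotypeAlignment) -> HaplotypeAlignment:
    """Drop every site column containing at least one missing state."""
    keep = ~(alignment.sites == MISSING).any(axis=0)
    anc = (
        alignment.ancestral_states[keep]
        if alignment.ancestral_states is not None
        else None
    )
    return HaplotypeAlignment(
        alignment.sample_ids,
        alignment.populations,
        alignment.sites[:, keep],
        alignment.locus_length_bp,
        ancestral_states=anc,
    )


def collapse_haplotypes(
    alignment: HaplotypeAlignment, missing_policy: str = "complete_deletion"
) -> HaplotypeTable:
    """Merge identical state vectors into haplotypes and count per population.

    Haplotype identity must be defined on a common site set, so under
    ``complete_deletion`` (the default) any column with missing data is
    dropped first; under ``strict`` missing data raises.
    """
    if missing_policy == "complete_deletion":
        aln = complete_deletion(alignment)
        if alignment.n_sites > 0 and aln.n_sites == 0:
            raise DegenerateInputError(
                "no sites remain after complete deletion of missing data"
            )
    elif missing_policy == "strict":
        if (alignment.sites == MISSING).any():
            raise ValidationError("missing states present under strict policy")
        aln = alignment
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    seqs = ["".join(row) for row in aln.sites]
    order: dict[str, str] = {}
    for s in seqs:
        if s not in order:
            order[s] = f"H{len(order) + 1:04d}"
    pops = aln.population_codes()
    counts = pd.DataFrame(
        0, index=pops, columns=list(order.values()), dtype=int
    )
    for s, pop in zip(seqs, aln.populations):
        counts.loc[pop, order[s]] += 1
    return HaplotypeTable(
        haplotypes={hid: s for s, hid in order.items()}, counts=counts
    )


def pairwise_difference_matrix(
    alignment: HaplotypeAlignment, missing_policy: str = "pairwise_deletion"
) -> DistanceMatrix:
    """Sample-by-sample counts of differing sites.

    Under ``pairwise_deletion`` a pair is compared only at sites where both
    samples are non-missing; under ``complete_deletion`` columns with any
    missing state are dropped globally first.  Entries are difference counts
    (not per-bp); the triangle inequality is not guaranteed under pairwise
    deletion.
    """
    if alignment.n_samples < 2:
        raise DegenerateInputError("need >= 2 samples for pairwise differences")
    if missing_policy == "complete_deletion":
        aln = complete_deletion(alignment)
        sites = aln.sites
        missing_mask = np.zeros(sites.shape, dtype=bool)
    elif missing_policy == "pairwise_deletion":
        sites = alignment.sites
        missing_mask = sites == MISSING
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    n = sites.shape[0]
    d = np.zeros((n, n), dtype=float)
    # site-state codes for fast vectorized comparison
    codes = sites.view(np.uint32).reshape(n, -1) if sites.size else np.zeros((n, 0))
    for i in range(n):
        neq = codes[i] != codes
        comparable = ~(missing_mask[i] | missing_mask)
        d[i] = (neq & comparable).sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        labels=list(alignment.sample_ids), values=d, kind="pairwise_diff"
    )


# ---------------------------------------------------------------------------
# Writers for labelled matrices and generic tables


def write_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a labelled square matrix as TSV (round-trip safe to 12 sig figs)."""
    if len(matrix.labels) == 0:
        warnings.warn("writing empty matrix: header-only file", stacklevel=2)
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, sep="\t", float_format="%.12g", quoting=csv.QUOTE_MINIMAL)


def read_matrix(path: str | Path, kind: str = "pairwise_diff") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(
        labels=[str(x) for x in df.index], values=df.to_numpy(dtype=float), kind=kind
    )


def write_table(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write a list of records as a TSV table."""
    df = pd.DataFrame(list(rows))
    if df.empty:
        warnings.warn("writing empty table", stacklevel=2)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
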