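"""Data model, file I/O, validation and variant alignment for summarized MR inputs.

A Mendelian randomization analysis from summarized data needs three pieces:
per-variant associations with the exposure (beta and SE from univariable GWAS
regressions), the same for the outcome, and a signed correlation (LD) matrix
over the same variants, typically estimated from a reference panel.  This
module defines the containers (:class:`SummarySet`, :class:`LDMatrix`), the
text readers/writers, and :func:`align`, which intersects and harmonizes the
two association tables and subsets the LD matrix to match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryHalf",
    "SummarySet",
    "LDMatrix",
    "FormatError",
    "ValidationError",
    "read_summary",
    "write_summary",
    "read_ld",
    "write_ld",
    "compute_ld",
    "align",
]

#: Default column names for summary-statistics files.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "id": "snp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "eaf": "eaf",
}

# Bounded repair of float noise in correlation entries; anything worse than
# this is treated as a data error because near-singular inverses magnify
# small inconsistencies.
CLIP_TOLERANCE = 1e-6
SYMMETRY_TOLERANCE = 1e-6
DIAGONAL_TOLERANCE = 1e-3

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """A file could not be parsed in the expected layout."""


class ValidationError(ValueError):
    """Parsed values violate an invariant (e.g. non-positive SE)."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class SummaryHalf:
    """One side (exposure or outcome) of a summarized dataset.

    Holds per-variant association estimates and standard errors from
    univariable regressions, with optional allele and frequency annotation.
    """

    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    effect_allele: list[str] | None = None
    other_allele: list[str] | None = None
    eaf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.beta = _as_float_array(self.beta, "beta")
        self.se = _as_float_array(self.se, "se")
        j = len(self.variant_ids)
        if not (len(self.beta) == len(self.se) == j):
            raise ValidationError("variant_ids, beta and se must have equal length")
        if j == 0:
            raise ValidationError("at least one variant is required")
        if len(set(self.variant_ids)) != j:
            raise ValidationError("duplicate variant identifiers")
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("non-finite beta values")
        bad = np.flatnonzero(~(np.isfinite(self.se) & (self.se > 0)))
        if bad.size:
            raise ValidationError(
                f"standard errors must be positive and finite (rows {bad.tolist()})"
            )
        if self.eaf is not None:
            self.eaf = _as_float_array(self.eaf, "eaf")
            if len(self.eaf) != j:
                raise ValidationError("eaf length mismatch")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, index: Sequence[int]) -> "SummaryHalf":
        idx = list(index)
        return SummaryHalf(
            variant_ids=[self.variant_ids[i] for i in idx],
            beta=self.beta[idx],
            se=self.se[idx],
            effect_allele=None
            if self.effect_allele is None
            else [self.effect_allele[i] for i in idx],
            other_allele=None
            if self.other_allele is None
            else [self.other_allele[i] for i in idx],
            eaf=None if self.eaf is None else self.eaf[idx],
        )


@dataclass
class SummarySet:
    """Aligned exposure and outcome summary statistics for one gene region.

    ``beta_x``/``se_x`` are the per-allele associations with the exposure,
    ``beta_y``/``se_y`` with the outcome (e.g. a log odds ratio), in a shared
    variant order.  ``eaf`` is optional and only used for variance-explained
    annotation.
    """

    variant_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        j = len(self.variant_ids)
        if j == 0:
            raise ValidationError("at least one variant is required")
        if len(set(self.variant_ids)) != j:
            raise ValidationError("duplicate variant identifiers")
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            arr = _as_float_array(getattr(self, name), name)
            setattr(self, name, arr)
            if len(arr) != j:
                raise ValidationError(f"{name} length {len(arr)} != {j} variants")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in {name}")
        for name in ("se_x", "se_y"):
            if not np.all(getattr(self, name) > 0):
                raise ValidationError(f"{name} must be strictly positive")
        if self.eaf is not None:
            self.eaf = _as_float_array(self.eaf, "eaf")
            if len(self.eaf) != j:
                raise ValidationError("eaf length mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, index: Sequence[int]) -> "SummarySet":
        idx = list(index)
        return SummarySet(
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_x=self.beta_x[idx],
            se_x=self.se_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            eaf=None if self.eaf is None else self.eaf[idx],
        )

    def subset_ids(self, ids: Sequence[str]) -> "SummarySet":
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            return self.subset([pos[v] for v in ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown variant id {exc.args[0]!r}") from None


@dataclass
class LDMatrix:
    """Signed pairwise correlation matrix over an ordered list of variants."""

    variant_ids: list[str]
    rho: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        rho = np.asarray(self.rho, dtype=float)
        j = len(self.variant_ids)
        if rho.shape != (j, j):
            raise ValidationError(f"rho shape {rho.shape} does not match {j} variants")
        if len(set(self.variant_ids)) != j:
            raise ValidationError("duplicate variant identifiers")
        if not np.all(np.isfinite(rho)):
            raise ValidationError("non-finite correlation entries")
        if np.max(np.abs(rho - rho.T)) > 1e-8:
            raise ValidationError("correlation matrix is not symmetric")
        if np.max(np.abs(np.diag(rho) - 1.0)) > 1e-8:
            raise ValidationError("correlation matrix diagonal must be 1")
        excess = np.max(np.abs(rho)) - 1.0
        if excess > CLIP_TOLERANCE:
            raise ValidationError(
                f"correlation entries exceed [-1, 1] by {excess:.3g} (> {CLIP_TOLERANCE:g})"
            )
        if excess > 0:
            rho = np.clip(rho, -1.0, 1.0)
        self.rho = rho

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, index: Sequence[int]) -> "LDMatrix":
        idx = list(index)
        return LDMatrix(
            variant_ids=[self.variant_ids[i] for i in idx],
            rho=self.rho[np.ix_(idx, idx)],
        )

    def subset_ids(self, ids: Sequence[str]) -> "LDMatrix":
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            return self.subset([pos[v] for v in ids])
        except KeyError as exc:
            raise ValidationError(f"unknown variant id {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Summary-statistics I/O
# ---------------------------------------------------------------------------

def read_summary(path, column_map: Mapping[str, str] | None = None) -> SummaryHalf:
    """Read one side of a summarized dataset from delimited text.

    The file must be tab- or comma-delimited with a header.  Required columns
    (after applying ``column_map``, defaults in :data:`DEFAULT_COLUMNS`):
    variant id, beta, se.  Allele and frequency columns are optional and
    enable harmonization in :func:`align`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from None
    for key in ("id", "beta", "se"):
        if cols[key] not in df.columns:
            raise FormatError(
                f"missing required column {cols[key]!r} (for {key}) in {path}; "
                f"found {list(df.columns)}"
            )
    beta = pd.to_numeric(df[cols["beta"]], errors="coerce").to_numpy(dtype=float)
    se = pd.to_numeric(df[cols["se"]], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~(np.isfinite(beta) & np.isfinite(se)))
    if bad.size:
        raise ValidationError(f"non-finite beta/se in {path} at rows {bad.tolist()}")
    nonpos = np.flatnonzero(se <= 0)
    if nonpos.size:
        raise ValidationError(
            f"non-positive standard error in {path} at rows {nonpos.tolist()}"
        )
    kwargs = {}
    for key, attr in (("effect_allele", "effect_allele"), ("other_allele", "other_allele")):
        if cols[key] in df.columns:
            kwargs[attr] = df[cols[key]].astype(str).str.upper().tolist()
    if cols["eaf"] in df.columns:
        kwargs["eaf"] = pd.to_numeric(df[cols["eaf"]], errors="coerce").to_numpy(dtype=float)
    return SummaryHalf(
        variant_ids=df[cols["id"]].astype(str).tolist(),
        beta=beta,
        se=se,
        **kwargs,
    )


def write_summary(half: SummaryHalf, path, column_map: Mapping[str, str] | None = None,
                  sep: str = "\t") -> None:
    """Write a :class:`SummaryHalf` as delimited text (inverse of :func:`read_summary`)."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    data = {cols["id"]: half.variant_ids}
    if half.effect_allele is not None:
        data[cols["effect_allele"]] = half.effect_allele
    if half.other_allele is not None:
        data[cols["other_allele"]] = half.other_allele
    data[cols["beta"]] = half.beta
    data[cols["se"]] = half.se
    if half.eaf is not None:
        data[cols["eaf"]] = half.eaf
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# LD-matrix I/O
# ---------------------------------------------------------------------------

def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_ld(path) -> LDMatrix:
    """Read an LD matrix from text.

    Two dialects are accepted:

    * a square whitespace-delimited numeric matrix, optionally preceded by a
      single header row of variant identifiers;
    * PLINK-style long format with three columns ``ID_A ID_B R`` listing
      pairwise correlations (missing pairs default to 0, diagonal to 1).

    Mild asymmetry (at most ``1e-6``) is repaired by averaging; anything
    larger is an error, as is a diagonal entry deviating from 1 by more than
    ``1e-3`` or any entry outside ``[-1, 1]`` by more than ``1e-6``.
    """
    with open(path) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows:
        raise FormatError(f"{path} is empty")

    first = rows[0]
    if len(first) == 3 and not _is_number(first[0]) and not _is_number(first[1]) \
            and (_is_number(first[2]) or first[2].upper() in {"R", "RHO"}):
        return _read_ld_long(rows, path)

    header: list[str] | None = None
    if not all(_is_number(tok) for tok in first):
        header = [str(tok) for tok in first]
        rows = rows[1:]
    try:
        mat = np.array([[float(tok) for tok in row] for row in rows], dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric entry in {path}: {exc}") from None
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: LD matrix is not square (shape {mat.shape})")
    ids = header if header is not None else [f"v{i + 1}" for i in range(mat.shape[0])]
    if len(ids) != mat.shape[0]:
        raise FormatError(f"{path}: header has {len(ids)} ids for {mat.shape[0]} rows")
    return _validate_raw_ld(ids, mat, path)


def _read_ld_long(rows: list[list[str]], path) -> LDMatrix:
    if not _is_number(rows[0][2]):  # header row such as "ID_A ID_B R"
        rows = rows[1:]
    ids: list[str] = []
    seen: dict[str, int] = {}
    triples = []
    for row in rows:
        if len(row) != 3:
            raise FormatError(f"{path}: long-format rows need 3 columns, got {row}")
        a, b, r = row[0], row[1], float(row[2])
        for v in (a, b):
            if v not in seen:
                seen[v] = len(ids)
                ids.append(v)
        triples.append((seen[a], seen[b], r))
    j = len(ids)
    mat = np.eye(j)
    for ia, ib, r in triples:
        mat[ia, ib] = r
        mat[ib, ia] = r
    return _validate_raw_ld(ids, mat, path)


def _validate_raw_ld(ids: list[str], mat: np.ndarray, path) -> LDMatrix:
    asym = np.max(np.abs(mat - mat.T)) if mat.size else 0.0
    if asym > SYMMETRY_TOLERANCE:
        raise ValidationError(f"{path}: asymmetry {asym:.3g} exceeds {SYMMETRY_TOLERANCE:g}")
    mat = 0.5 * (mat + mat.T)
    diag_dev = np.max(np.abs(np.diag(mat) - 1.0))
    if diag_dev > DIAGONAL_TOLERANCE:
        raise ValidationError(
            f"{path}: diagonal deviates from 1 by {diag_dev:.3g} (> {DIAGONAL_TOLERANCE:g})"
        )
    np.fill_diagonal(mat, 1.0)
    excess = np.max(np.abs(mat)) - 1.0
    if excess > CLIP_TOLERANCE:
        raise ValidationError(
            f"{path}: correlation magnitude exceeds 1 by {excess:.3g}"
        )
    return LDMatrix(variant_ids=ids, rho=mat)


def write_ld(ld: LDMatrix, path) -> None:
    """Write an LD matrix in the square dialect with an ID header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(ld.variant_ids) + "\n")
        for row in ld.rho:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def compute_ld(dosages: np.ndarray, variant_ids: Sequence[str]) -> LDMatrix:
    """Pearson correlation matrix of genotype dosage columns.

    Monomorphic variants (zero dosage variance) cannot contribute a defined
    correlation; they are excluded with a warning listing their identifiers,
    mirroring the handling of monomorphic reference-panel variants.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2:
        raise ValidationError("dosages must be an N x J matrix")
    n, j = dosages.shape
    if n < 2:
        raise ValidationError(f"need at least 2 individuals, got {n}")
    if len(variant_ids) != j:
        raise ValidationError("variant_ids length does not match dosage columns")
    variances = dosages.var(axis=0)
    keep = variances > 0
    if not np.all(keep):
        dropped = [str(variant_ids[i]) for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"excluding {len(dropped)} monomorphic variant(s): {dropped}",
            stacklevel=2,
        )
    ids = [str(variant_ids[i]) for i in np.flatnonzero(keep)]
    if not ids:
        raise ValidationError("all variants are monomorphic")
    rho = np.corrcoef(dosages[:, keep], rowvar=False)
    rho = np.atleast_2d(rho)
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return LDMatrix(variant_ids=ids, rho=rho)


# ---------------------------------------------------------------------------
# Alignment / harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def align(
    exposure: SummaryHalf,
    outcome: SummaryHalf,
    ld: LDMatrix,
) -> tuple[SummarySet, LDMatrix]:
    """Intersect, order and harmonize exposure/outcome summaries with an LD matrix.

    Variants are kept in exposure order.  When both tables carry allele
    columns, outcome rows whose effect/other alleles are swapped relative to
    the exposure have ``beta_y`` sign-flipped (allele-frequency ``eaf`` is
    complemented too); alleles matching only on the opposite strand are
    treated the same way after complementing; strand-ambiguous (palindromic)
    variants with mismatching alleles are dropped with a warning, as is any
    unreconcilable allele pair.  Without allele columns a shared effect-allele
    convention is assumed and a warning is emitted.
    """
    out_pos = {v: i for i, v in enumerate(outcome.variant_ids)}
    ld_pos = {v: i for i, v in enumerate(ld.variant_ids)}
    common = [v for v in exposure.variant_ids
              if v in out_pos and v in ld_pos]
    if not common:
        raise ValidationError("no variant is shared by exposure, outcome and LD matrix")

    have_alleles = (
        exposure.effect_allele is not None and outcome.effect_allele is not None
    )
    if not have_alleles:
        warnings.warn(
            "no allele columns: assuming a shared effect-allele convention",
            stacklevel=2,
        )

    exp_pos = {v: i for i, v in enumerate(exposure.variant_ids)}
    kept: list[str] = []
    flip: list[bool] = []
    dropped: list[str] = []
    for v in common:
        if not have_alleles:
            kept.append(v)
            flip.append(False)
            continue
        ie, io = exp_pos[v], out_pos[v]
        ea_e = exposure.effect_allele[ie]
        oa_e = exposure.other_allele[ie] if exposure.other_allele else None
        ea_o = outcome.effect_allele[io]
        oa_o = outcome.other_allele[io] if outcome.other_allele else None
        if ea_o == ea_e and (oa_e is None or oa_o is None or oa_o == oa_e):
            kept.append(v); flip.append(False)
        elif oa_e is not None and ea_o == oa_e and (oa_o is None or oa_o == ea_e):
            kept.append(v); flip.append(True)
        elif oa_e is not None and _is_palindromic(ea_e, oa_e):
            dropped.append(v)  # palindromic mismatch: strand is unresolvable
        elif ea_o == _COMPLEMENT.get(ea_e) and (
            oa_e is None or oa_o is None or oa_o == _COMPLEMENT.get(oa_e)
        ):
            kept.append(v); flip.append(False)
        elif oa_e is not None and ea_o == _COMPLEMENT.get(oa_e) and (
            oa_o is None or oa_o == _COMPLEMENT.get(ea_e)
        ):
            kept.append(v); flip.append(True)
        else:
            dropped.append(v)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} variant(s) with irreconcilable alleles: {dropped}",
            stacklevel=2,
        )
    if not kept:
        raise ValidationError("no variant survived allele harmonization")

    exp_idx = [exp_pos[v] for v in kept]
    out_idx = [out_pos[v] for v in kept]
    sign = np.where(np.asarray(flip), -1.0, 1.0)
    eaf = None
    if exposure.eaf is not None:
        eaf = exposure.eaf[exp_idx]
    data = SummarySet(
        variant_ids=kept,
        beta_x=exposure.beta[exp_idx],
        se_x=exposure.se[exp_idx],
        beta_y=outcome.beta[out_idx] * sign,
        se_y=outcome.se[out_idx],
        eaf=eaf,
    )
    ld_sub = ld.subset([ld_pos[v] for v in kept])
    return data, ld_sub
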