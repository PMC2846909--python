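"""Readers and writers for the MACH imputation file dialect and friends.

The genotype side of a run consists of three whitespace-delimited files as
written by the MACH imputation software:

``mlinfo``
    per-SNP metadata: name, alleles, frequency of allele 1, minor-allele
    frequency, imputation quality and Rsq, one row per SNP;
``mldose``
    per-sample expected allele-1 counts ("dosages") in [0, 2], one row per
    sample, one column per SNP;
``mlprob``
    per-sample posterior genotype probabilities, two columns per SNP
    (P(AA), P(AB)); P(BB) is implied as the complement.

Sample rows start with a ``famid->id`` token followed by the literal
``MLDOSE``/``MLPROB`` tag.  The id is the substring after ``->``; a token
without ``->`` is used verbatim.  Missing dosage cells are coded ``NA``,
``nan`` or a negative number.

The phenotype table is whitespace-delimited with a header, first column the
sample id, then the outcome (two columns, time and status, for survival),
then covariates; ``NA`` (case-insensitive) is the only missing code.

The mixed-model hand-off file (``IVFile``) holds the inverse of the fitted
phenotypic variance-covariance matrix: a header row of ids, then the dense
symmetric matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SnpInfo",
    "DoseMatrix",
    "ProbMatrix",
    "PhenoTable",
    "InverseVarCov",
    "read_mlinfo",
    "write_mlinfo",
    "read_mldose",
    "write_mldose",
    "read_mlprob",
    "write_mlprob",
    "read_phenotype",
    "write_phenotype",
    "read_inverse_varcov",
    "write_inverse_varcov",
    "read_map",
    "align_samples",
    "write_results",
]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


_MLINFO_COLUMNS = ["SNP", "Al1", "Al2", "Freq1", "MAF", "Quality", "Rsq"]
_MISSING_TOKENS = {"na", "nan"}


@dataclasses.dataclass
class SnpInfo:
    """One mlinfo record: allele coding and imputation quality for a SNP."""

    snp_name: str
    allele1: str
    allele2: str
    freq1: float
    maf: float
    quality: float
    rsq: float

    def validate(self) -> None:
        if not (0.0 <= self.freq1 <= 1.0):
            raise FormatError(f"{self.snp_name}: Freq1 {self.freq1} outside [0,1]")
        if abs(self.maf - min(self.freq1, 1.0 - self.freq1)) > 1e-6:
            raise FormatError(
                f"{self.snp_name}: MAF {self.maf} != min(Freq1, 1-Freq1)"
            )
        for label, v in (("Quality", self.quality), ("Rsq", self.rsq)):
            if not (0.0 <= v <= 1.0):
                raise FormatError(f"{self.snp_name}: {label} {v} outside [0,1]")


@dataclasses.dataclass
class DoseMatrix:
    """Expected allele-1 dosage per sample (rows) and SNP (columns)."""

    sample_ids: list[str]
    snp_names: list[str]
    dose: np.ndarray  # (n, m) float; undefined where missing
    missing: np.ndarray  # (n, m) bool

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = self.dose.shape
        if n != len(self.sample_ids) or m != len(self.snp_names):
            raise FormatError("dose matrix shape does not match id lists")
        ok = self.missing | ((self.dose >= -1e-6) & (self.dose <= 2 + 1e-6))
        if not ok.all():
            raise FormatError("dose values outside [0,2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_names)

    def take_samples(self, idx: np.ndarray) -> "DoseMatrix":
        return DoseMatrix(
            [self.sample_ids[i] for i in idx],
            self.snp_names,
            self.dose[idx],
            self.missing[idx],
        )


@dataclasses.dataclass
class ProbMatrix:
    """Posterior genotype probabilities (P_AA, P_AB) per sample and SNP.

    P_BB is implied as ``1 - p_AA - p_AB``.
    """

    sample_ids: list[str]
    snp_names: list[str]
    p_AA: np.ndarray  # (n, m)
    p_AB: np.ndarray  # (n, m)
    missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.p_AA = np.asarray(self.p_AA, dtype=float)
        self.p_AB = np.asarray(self.p_AB, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.p_AA.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = self.p_AA.shape
        if self.p_AB.shape != (n, m):
            raise FormatError("p_AA and p_AB shapes differ")
        if n != len(self.sample_ids) or m != len(self.snp_names):
            raise FormatError("probability matrix shape does not match id lists")
        obs = ~self.missing
        if obs.any():
            pa, pb = self.p_AA[obs], self.p_AB[obs]
            if (pa < -1e-6).any() or (pb < -1e-6).any():
                raise FormatError("negative genotype probability")
            if ((pa + pb) > 1 + 1e-6).any():
                raise FormatError("p_AA + p_AB exceeds 1")

    @property
    def p_BB(self) -> np.ndarray:
        return 1.0 - self.p_AA - self.p_AB

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_names)

    def take_samples(self, idx: np.ndarray) -> "ProbMatrix":
        return ProbMatrix(
            [self.sample_ids[i] for i in idx],
            self.snp_names,
            self.p_AA[idx],
            self.p_AB[idx],
            self.missing[idx],
        )


OutcomeKind = Literal["quantitative", "binary", "survival"]


@dataclasses.dataclass
class PhenoTable:
    """Phenotype table: outcome, covariates, per-row missingness mask."""

    sample_ids: list[str]
    outcome_kind: OutcomeKind
    outcome: np.ndarray  # (n,) or (n, 2) [time, status] for survival
    covariates: np.ndarray  # (n, k)
    covariate_names: list[str]
    missing: np.ndarray  # (n,) bool: outcome or any covariate missing

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicated sample id in phenotype table")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def take_samples(self, idx: np.ndarray) -> "PhenoTable":
        return PhenoTable(
            [self.sample_ids[i] for i in idx],
            self.outcome_kind,
            self.outcome[idx],
            self.covariates[idx],
            self.covariate_names,
            self.missing[idx],
        )


@dataclasses.dataclass
class InverseVarCov:
    """Inverse phenotypic variance-covariance matrix keyed by sample id."""

    sample_ids: list[str]
    omega_inv: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.omega_inv, dtype=float)
        n = len(self.sample_ids)
        if a.shape != (n, n):
            raise FormatError("inverse variance-covariance matrix is not square")
        if not np.allclose(a, a.T, atol=1e-8):
            raise FormatError("inverse variance-covariance matrix not symmetric")
        try:
            np.linalg.cholesky(a)
        except np.linalg.LinAlgError as exc:
            raise FormatError(
                "inverse variance-covariance matrix not positive-definite"
            ) from exc
        self.omega_inv = a

    def take_samples(self, idx: np.ndarray) -> "InverseVarCov":
        return InverseVarCov(
            [self.sample_ids[i] for i in idx],
            self.omega_inv[np.ix_(idx, idx)],
        )


# ---------------------------------------------------------------------------
# mlinfo


def read_mlinfo(path) -> list[SnpInfo]:
    with open(path) as fh:
        header = fh.readline().split()
        if header != _MLINFO_COLUMNS:
            missing = [c for c in _MLINFO_COLUMNS if c not in header]
            if missing:
                raise FormatError(
                    f"{path}: mlinfo header missing column(s) {', '.join(missing)}"
                )
            raise FormatError(
                f"{path}: mlinfo header columns out of order: {header}"
            )
        out: list[SnpInfo] = []
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 fields, got {len(tok)}")
            try:
                rec = SnpInfo(
                    snp_name=tok[0],
                    allele1=tok[1],
                    allele2=tok[2],
                    freq1=float(tok[3]),
                    maf=float(tok[4]),
                    quality=float(tok[5]),
                    rsq=float(tok[6]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            rec.validate()
            out.append(rec)
    return out


def write_mlinfo(info: Sequence[SnpInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(_MLINFO_COLUMNS) + "\n")
        for r in info:
            fh.write(
                f"{r.snp_name} {r.allele1} {r.allele2} "
                f"{r.freq1:.6f} {r.maf:.6f} {r.quality:.6f} {r.rsq:.6f}\n"
            )


# ---------------------------------------------------------------------------
# mldose / mlprob

def _split_sample_row(tok0: str) -> str:
    return tok0.split("->", 1)[1] if "->" in tok0 else tok0


def _parse_cell(token: str, path, lineno: int, col: int) -> tuple[float, bool]:
    """Parse one genotype cell -> (value, is_missing)."""
    if token.lower() in _MISSING_TOKENS:
        return np.nan, True
    try:
        v = float(token)
    except ValueError as exc:
        raise FormatError(
            f"{path}:{lineno}: unparsable value {token!r} in genotype column {col}"
        ) from exc
    if np.isnan(v) or v < 0:
        return np.nan, True
    return v, False


def read_mldose(path, info: Sequence[SnpInfo]) -> DoseMatrix:
    m = len(info)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    miss: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 2 or tok[1].upper() != "MLDOSE":
                raise FormatError(f"{path}:{lineno}: expected 'MLDOSE' tag")
            if len(tok) - 2 != m:
                raise FormatError(
                    f"{path}:{lineno}: {len(tok) - 2} dosage fields for {m} SNPs"
                )
            ids.append(_split_sample_row(tok[0]))
            vals = np.empty(m)
            ms = np.zeros(m, dtype=bool)
            for j, t in enumerate(tok[2:]):
                v, is_na = _parse_cell(t, path, lineno, j + 1)
                if not is_na and v > 2 + 1e-6:
                    raise FormatError(
                        f"{path}:{lineno}: dose {v} outside [0,2] in column {j + 1}"
                    )
                vals[j] = v
                ms[j] = is_na
            rows.append(vals)
            miss.append(ms)
    return DoseMatrix(ids, [r.snp_name for r in info], np.array(rows), np.array(miss))


def write_mldose(dose: DoseMatrix, path, famid: str = "1") -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(dose.sample_ids):
            cells = [
                "NA" if dose.missing[i, j] else f"{dose.dose[i, j]:.4f}"
                for j in range(dose.n_snps)
            ]
            fh.write(f"{famid}->{sid} MLDOSE " + " ".join(cells) + "\n")


def read_mlprob(path, info: Sequence[SnpInfo]) -> ProbMatrix:
    m = len(info)
    ids: list[str] = []
    paa: list[np.ndarray] = []
    pab: list[np.ndarray] = []
    miss: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 2 or tok[1].upper() != "MLPROB":
                raise FormatError(f"{path}:{lineno}: expected 'MLPROB' tag")
            vals = tok[2:]
            if len(vals) % 2:
                raise FormatError(
                    f"{path}:{lineno}: odd number of genotype probability fields"
                )
            if len(vals) != 2 * m:
                raise FormatError(
                    f"{path}:{lineno}: {len(vals)} probability fields for {m} SNPs"
                )
            ids.append(_split_sample_row(tok[0]))
            a = np.empty(m)
            b = np.empty(m)
            ms = np.zeros(m, dtype=bool)
            for j in range(m):
                va, na_a = _parse_cell(vals[2 * j], path, lineno, 2 * j + 1)
                vb, na_b = _parse_cell(vals[2 * j + 1], path, lineno, 2 * j + 2)
                if (not na_a and va > 1 + 1e-6) or (not na_b and vb > 1 + 1e-6):
                    raise FormatError(
                        f"{path}:{lineno}: probability outside [0,1] for SNP {j + 1}"
                    )
                a[j], b[j] = va, vb
                ms[j] = na_a or na_b
            paa.append(a)
            pab.append(b)
            miss.append(ms)
    return ProbMatrix(
        ids, [r.snp_name for r in info], np.array(paa), np.array(pab), np.array(miss)
    )


def write_mlprob(probs: ProbMatrix, path, famid: str = "1") -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(probs.sample_ids):
            cells = []
            for j in range(probs.n_snps):
                if probs.missing[i, j]:
                    cells += ["NA", "NA"]
                else:
                    cells += [f"{probs.p_AA[i, j]:.6f}", f"{probs.p_AB[i, j]:.6f}"]
            fh.write(f"{famid}->{sid} MLPROB " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# phenotype table


def read_phenotype(path, outcome_kind: OutcomeKind = "quantitative") -> PhenoTable:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=[], keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: phenotype file needs an id and an outcome column")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample id")

    def col(j: int) -> np.ndarray:
        s = df.iloc[:, j].str.strip()
        na = s.str.lower().isin(_MISSING_TOKENS)
        vals = pd.to_numeric(s.mask(na), errors="coerce")
        bad = vals.isna() & ~na
        if bad.any():
            r = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric value {s.iloc[r]!r} in column "
                f"{df.columns[j]!r}, row {r + 2}"
            )
        return vals.to_numpy(dtype=float)

    if outcome_kind == "survival":
        if df.shape[1] < 3:
            raise FormatError(f"{path}: survival outcome needs time and status columns")
        time = col(1)
        status = col(2)
        obs = ~np.isnan(status)
        if not np.isin(status[obs], (0.0, 1.0)).all():
            raise FormatError(f"{path}: survival status outside {{0,1,NA}}")
        if (time[~np.isnan(time)] <= 0).any():
            raise FormatError(f"{path}: non-positive survival time")
        outcome = np.column_stack([time, status])
        first_cov = 3
        out_missing = np.isnan(time) | np.isnan(status)
    else:
        y = col(1)
        if outcome_kind == "binary":
            obs = ~np.isnan(y)
            if not np.isin(y[obs], (0.0, 1.0)).all():
                raise FormatError(f"{path}: binary outcome outside {{0,1,NA}}")
        outcome = y
        first_cov = 2
        out_missing = np.isnan(y)

    cov_names = list(df.columns[first_cov:])
    if cov_names:
        covs = np.column_stack([col(j) for j in range(first_cov, df.shape[1])])
    else:
        covs = np.empty((len(ids), 0))
    missing = out_missing | (np.isnan(covs).any(axis=1) if covs.size else False)
    return PhenoTable(ids, outcome_kind, outcome, covs, cov_names, np.asarray(missing))


def write_phenotype(pheno: PhenoTable, path) -> None:
    def fmt(v: float) -> str:
        return "NA" if np.isnan(v) else f"{v:.6g}"

    with open(path, "w") as fh:
        if pheno.outcome_kind == "survival":
            out_cols = ["time", "status"]
        else:
            out_cols = ["outcome"]
        fh.write(" ".join(["id"] + out_cols + pheno.covariate_names) + "\n")
        out2d = np.atleast_2d(pheno.outcome.T).T
        for i, sid in enumerate(pheno.sample_ids):
            row = [sid] + [fmt(v) for v in out2d[i]] + [
                fmt(v) for v in pheno.covariates[i]
            ]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# inverse variance-covariance (IVFile) and map


def read_inverse_varcov(path) -> InverseVarCov:
    with open(path) as fh:
        ids = fh.readline().split()
        if not ids:
            raise FormatError(f"{path}: empty IVFile header")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != len(ids):
                raise FormatError(
                    f"{path}:{lineno}: {len(tok)} fields for {len(ids)} ids"
                )
            try:
                rows.append([float(t) for t in tok])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry") from exc
    if len(rows) != len(ids):
        raise FormatError(f"{path}: {len(rows)} matrix rows for {len(ids)} ids")
    return InverseVarCov(ids, np.array(rows))


def write_inverse_varcov(ivc: InverseVarCov, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ivc.sample_ids) + "\n")
        for row in ivc.omega_inv:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_map(path) -> pd.DataFrame:
    """Map file (SNP, chromosome, position): passed through to output verbatim."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: map file needs SNP, chromosome, position columns")
    df.columns = ["SNP", "chrom", "position"] + list(df.columns[3:])
    return df.iloc[:, :3]


# ---------------------------------------------------------------------------
# sample alignment


def align_samples(
    pheno: PhenoTable,
    geno,
    omega_inv: Optional[InverseVarCov] = None,
):
    """Restrict all inputs to the id intersection, in phenotype order.

    Returns ``(pheno, geno, omega_inv, n_dropped_pheno, n_dropped_geno)``.
    The inverse variance-covariance matrix, when supplied, must cover every
    retained analysis id: it is fitted jointly and cannot be subset-imputed.
    """
    geno_pos = {sid: i for i, sid in enumerate(geno.sample_ids)}
    keep = [sid for sid in pheno.sample_ids if sid in geno_pos]
    if not keep:
        raise FormatError("phenotype and genotype files share no sample ids")
    if omega_inv is not None:
        missing = [sid for sid in keep if sid not in set(omega_inv.sample_ids)]
        if missing:
            raise FormatError(
                "inverse variance-covariance matrix lacks analysis id(s): "
                + ", ".join(missing[:5])
            )
    n_dropped_pheno = pheno.n_samples - len(keep)
    n_dropped_geno = geno.n_samples - len(keep)

    ph_pos = {sid: i for i, sid in enumerate(pheno.sample_ids)}
    ph_idx = np.array([ph_pos[sid] for sid in keep])
    g_idx = np.array([geno_pos[sid] for sid in keep])
    pheno2 = pheno.take_samples(ph_idx)
    geno2 = geno.take_samples(g_idx)
    omega2 = None
    if omega_inv is not None:
        om_pos = {sid: i for i, sid in enumerate(omega_inv.sample_ids)}
        omega2 = omega_inv.take_samples(np.array([om_pos[sid] for sid in keep]))
    return pheno2, geno2, omega2, n_dropped_pheno, n_dropped_geno


# ---------------------------------------------------------------------------
# results


def write_results(
    results,
    info: Sequence[SnpInfo],
    path,
    snp_map: Optional[pd.DataFrame] = None,
    mean_dose: Optional[np.ndarray] = None,
) -> None:
    """Write one tab-delimited line per SNP.

    ``results`` is a sequence of :class:`probgwas.fixed_effects.FitResult`
    (or None for a SNP whose fit failed entirely); all results must share the
    same term layout.  Non-estimable fields are written as ``NA``.
    """
    if len(results) != len(info):
        raise ValueError(
            f"{len(results)} results for {len(info)} mlinfo records"
        )
    term_names = None
    for r in results:
        if r is not None and r.term_names:
            term_names = r.term_names
            break
    if term_names is None:
        term_names = ["SNP_add"]

    map_lookup = {}
    if snp_map is not None:
        map_lookup = {
            row.SNP: (row.chrom, row.position) for row in snp_map.itertuples()
        }

    def na(v, fmt="{:.6g}") -> str:
        return "NA" if v is None or (isinstance(v, float) and np.isnan(v)) else fmt.format(v)

    with open(path, "w") as fh:
        cols = ["name", "Al1", "Al2", "Freq1", "MAF", "Quality", "Rsq"]
        if map_lookup:
            cols += ["chrom", "position"]
        cols += ["n", "Mean_predictor_allele"]
        for t in term_names:
            cols += [f"beta_{t}", f"sebeta_{t}"]
        cols += ["chi2", "df"]
        fh.write("\t".join(cols) + "\n")
        for j, (res, rec) in enumerate(zip(results, info)):
            row = [
                rec.snp_name,
                rec.allele1,
                rec.allele2,
                f"{rec.freq1:.4f}",
                f"{rec.maf:.4f}",
                f"{rec.quality:.4f}",
                f"{rec.rsq:.4f}",
            ]
            if map_lookup:
                chrom, pos = map_lookup.get(rec.snp_name, ("NA", "NA"))
                row += [chrom, pos]
            row.append("NA" if res is None else str(res.n_used))
            md = None if mean_dose is None else mean_dose[j]
            row.append(na(md, "{:.4f}"))
            if res is None:
                row += ["NA", "NA"] * len(term_names) + ["NA", "NA"]
            else:
                for b, s in zip(res.beta, res.se):
                    row += [na(b), na(s)]
                row += [na(res.chi2_global), str(res.df)]
            fh.write("\t".join(row) + "\n")
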