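"""Reading, validation, filtering and transforms for methylation data.

Containers are thin wrappers around :class:`pandas.DataFrame` objects:

* :class:`BetaMatrix` — probes × samples methylation proportions in [0, 1],
  NaN for missing entries.
* :class:`MValueMatrix` — logit-transformed betas (finite everywhere).
* :class:`ProbeManifest` — per-probe genomic coordinates (1-based positions,
  Illumina MAPINFO convention). All interval types downstream (windows,
  regions, BED I/O) are 0-based half-open; the conversion happens exactly
  once, here.
* :class:`RegionSet` / :class:`Blacklist` — annotation intervals and probe
  exclusion lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylomeError",
    "ProbeManifest",
    "BetaMatrix",
    "MValueMatrix",
    "RegionSet",
    "Blacklist",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "filter_probes",
    "beta_to_m",
    "m_to_beta",
    "round_beta",
    "read_regions",
    "write_regions",
    "read_blacklist",
    "write_blacklist",
    "write_dmrs",
]

MISSING_TOKENS = ("NA", "NaN", "nan", "")

#: chromosome names excluded from all analyses (sex and mitochondrial)
EXCLUDED_CHROMS = frozenset({"chrx", "chry", "chrm", "chrmt", "x", "y", "m", "mt"})


class MethylomeError(ValueError):
    """Raised when an input file or matrix violates a structural rule."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ProbeManifest:
    """Genomic coordinates per probe.

    ``data`` is indexed by probe id with columns ``chrom`` (str), ``pos``
    (1-based bp, Int64 to allow missing) and ``strand`` (one of ``+ - .``,
    missing allowed before filtering).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand"}
        if not required.issubset(self.data.columns):
            raise MethylomeError(
                f"manifest must have columns {sorted(required)}, got {list(self.data.columns)}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise MethylomeError(f"duplicate probe id in manifest: {dup!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def sorted(self) -> "ProbeManifest":
        """Probes in (chrom, pos) order."""
        return ProbeManifest(self.data.sort_values(["chrom", "pos"], kind="stable"))

    def subset(self, probe_ids) -> "ProbeManifest":
        return ProbeManifest(self.data.loc[probe_ids])


@dataclass
class BetaMatrix:
    """Probes × samples matrix of methylation proportions."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise MethylomeError(f"duplicate probe id in beta matrix: {dup!r}")
        vals = self.data.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MethylomeError(
                f"beta value out of [0, 1] at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[probe_ids])


@dataclass
class MValueMatrix:
    """Probes × samples matrix of M values (logit of beta), finite everywhere
    thanks to clipping at ``epsilon``; missing entries stay missing."""

    data: pd.DataFrame
    epsilon: float = 0.001

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


@dataclass
class RegionSet:
    """Named set of (chrom, start, end) intervals, 0-based half-open."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise MethylomeError(
                    f"region {chrom}:{start}-{end} has start >= end"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass
class Blacklist:
    """Probe ids excluded from DMR calls (covariate-associated CpGs)."""

    probe_ids: frozenset[str] = frozenset()

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.probe_ids

    def __len__(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# beta matrix I/O
# ---------------------------------------------------------------------------


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path, delimiter: str | None = None) -> BetaMatrix:
    """Read a TSV/CSV beta matrix: header row of sample ids, first column
    probe ids, numeric cells in [0, 1] or a missing token (``NA`` / empty)."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
    )
    if df.shape[1] == 0:
        raise MethylomeError(f"{path}: malformed header, no sample columns found")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MethylomeError(f"{path}: non-numeric cell in beta matrix ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path, delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    beta.data.to_csv(path, sep=sep, na_rep="NA", index_label="probe_id")


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

_STRAND_MAP = {"+": "+", "-": "-", "F": "+", "R": "-", "f": "+", "r": "-"}


def _normalize_strand(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", ".") or s.upper() in ("NA", "NAN"):
        return None
    return _STRAND_MAP.get(s, s if s in ("+", "-") else None)


def read_manifest(path) -> ProbeManifest:
    """Read a probe manifest.

    Accepts an Illumina-style CSV with columns (IlmnID, CHR, MAPINFO, Strand)
    or a BED4 file (chrom, start, end, probe_id) — BED coordinates are
    converted to 1-based positions at read time.
    """
    path = str(path)
    if path.endswith(".bed"):
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise MethylomeError(f"{path}:{ln}: BED4 line needs 4 columns")
                chrom, start, _end, probe = parts[:4]
                strand = _normalize_strand(parts[5]) if len(parts) >= 6 else None
                rows.append((probe, chrom, int(start) + 1, strand))
        df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "strand"])
        df = df.set_index("probe_id")
    else:
        raw = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)
        cols = {c.lower(): c for c in raw.columns}

        def pick(*names):
            for n in names:
                if n in cols:
                    return cols[n]
            raise MethylomeError(
                f"{path}: manifest needs columns like (IlmnID, CHR, MAPINFO, Strand); "
                f"got {list(raw.columns)}"
            )

        df = pd.DataFrame(
            {
                "chrom": raw[pick("chr", "chrom", "chromosome")].to_numpy(),
                "pos": raw[pick("mapinfo", "pos", "position")].to_numpy(),
                "strand": raw[pick("strand")].map(_normalize_strand).to_numpy(),
            },
            index=pd.Index(
                raw[pick("ilmnid", "probe_id", "name")].astype(str), name="probe_id"
            ),
        )
    df["chrom"] = df["chrom"].astype("string")
    df.loc[df["chrom"].isin(["", "NA"]), "chrom"] = pd.NA
    df["pos"] = pd.array(pd.to_numeric(df["pos"], errors="coerce"), dtype="Int64")
    return ProbeManifest(df)


def filter_probes(
    manifest: ProbeManifest, beta: BetaMatrix | None = None
) -> tuple[ProbeManifest, BetaMatrix | None]:
    """Drop probes on sex/mitochondrial chromosomes or with any missing
    annotation field, from the manifest and (if given) the beta matrix.

    Relative probe order is preserved; idempotent. An empty result is allowed.
    """
    df = manifest.data
    chrom_ok = df["chrom"].notna() & ~df["chrom"].str.lower().isin(EXCLUDED_CHROMS)
    keep = chrom_ok & df["pos"].notna() & df["strand"].notna()
    kept = ProbeManifest(df.loc[keep])
    if beta is None:
        return kept, None
    shared = beta.probe_ids.intersection(kept.probe_ids)
    # preserve the beta matrix's own row order
    kept_beta = BetaMatrix(beta.data.loc[beta.probe_ids.isin(shared)])
    return kept, kept_beta


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def beta_to_m(beta: BetaMatrix, epsilon: float = 0.001) -> MValueMatrix:
    """Logit transform with clipping: M = ln(b / (1 - b)) after clipping b to
    [epsilon, 1 - epsilon]. Betas of exactly 0/1 (which occur after 3-digit
    rounding) therefore map to finite M values."""
    if not 0 < epsilon < 0.5:
        raise MethylomeError(f"epsilon must be in (0, 0.5), got {epsilon}")
    clipped = beta.data.clip(lower=epsilon, upper=1 - epsilon)
    m = np.log(clipped / (1 - clipped))
    return MValueMatrix(m, epsilon=epsilon)


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse logit; exact inverse of :func:`beta_to_m` up to the clipping."""
    return BetaMatrix(1 / (1 + np.exp(-m.data)))


def round_beta(beta: BetaMatrix, digits: int = 3) -> BetaMatrix:
    """Round betas half-to-even (numpy convention) to ``digits`` digits."""
    if digits < 0:
        raise MethylomeError("digits must be >= 0")
    return BetaMatrix(beta.data.round(digits))


# ---------------------------------------------------------------------------
# regions / blacklist / DMR output
# ---------------------------------------------------------------------------


def read_regions(path, name: str | None = None) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a RegionSet."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = re.split(r"\t", line)
            if len(parts) < 3:
                raise MethylomeError(f"{path}:{ln}: BED line needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise MethylomeError(f"{path}:{ln}: non-integer BED coordinate") from exc
            if start >= end:
                raise MethylomeError(f"{path}:{ln}: start >= end")
            intervals.append((parts[0], start, end))
    if name is None:
        name = str(path)
    return RegionSet(name=name, intervals=intervals)


def write_regions(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_blacklist(path) -> Blacklist:
    """One probe id per line; '#' comments and blank lines allowed."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return Blacklist(frozenset(ids))


def write_blacklist(blacklist: Blacklist, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(blacklist.probe_ids):
            fh.write(pid + "\n")


DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_probes",
    "p_aggregated",
    "p_aggregated_adjusted",
    "median_delta_beta",
    "direction",
    "significant",
    "blacklisted",
    "probe_ids",
]


def write_dmrs(dmrs, path, format: str = "tsv") -> None:
    """Write DMRs as a TSV table or BED (0-based half-open) file.

    ``dmrs`` is an iterable of :class:`solodmr.dmr_calling.Dmr`.
    """
    dmrs = list(dmrs)
    if format == "tsv":
        rows = [
            {
                "chrom": d.window.chrom,
                "start": d.window.start,
                "end": d.window.end,
                "n_probes": d.n_probes,
                "p_aggregated": d.p_aggregated,
                "p_aggregated_adjusted": d.p_aggregated_adjusted,
                "median_delta_beta": d.median_delta_beta,
                "direction": d.direction,
                "significant": d.significant,
                "blacklisted": d.blacklisted,
                "probe_ids": ";".join(d.window.probe_ids),
            }
            for d in dmrs
        ]
        pd.DataFrame(rows, columns=DMR_COLUMNS).to_csv(
            path, sep="\t", index=False, na_rep="NA"
        )
    elif format == "bed":
        with open(path, "w") as fh:
            for i, d in enumerate(dmrs):
                fh.write(
                    f"{d.window.chrom}\t{d.window.start}\t{d.window.end}\tdmr_{i}\n"
                )
    else:
        raise MethylomeError(f"unknown DMR output format: {format!r}")
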