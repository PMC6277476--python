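"""Genotype and site-table data model with Genepop / CSV readers and writers.

The package works on co-dominant diploid microsatellite data: each individual
carries an unordered pair of allele codes (positive integers, typically
fragment sizes or repeat counts) at each locus.  Missing data are encoded as
allele 0 in Genepop files and as a distinguished internal marker here — never
as a real allele.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeTable",
    "SiteTable",
    "ValidationReport",
    "read_genepop",
    "write_genepop",
    "read_long_csv",
    "write_long_csv",
    "read_site_table",
    "parse_dms",
    "validate",
    "load_packaged_sites",
    "load_packaged_diversity",
]

#: Internal missing-call marker.  Genepop writes it as 0, we never store 0.
MISSING: int = -9


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its format contract."""


@dataclass
class GenotypeTable:
    """Diploid allele calls for a set of individuals at a set of loci.

    Parameters
    ----------
    individuals
        Individual identifiers, one per row of ``calls``.
    loci
        Locus names, non-empty and duplicate-free.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``.  A call is
        either two positive allele codes or both entries :data:`MISSING`.
    populations
        Population id of each individual (parallel to ``individuals``).
    hierarchy
        Optional mapping ``population -> (mountain_range, environment_class)``
        used by hierarchical F-statistics.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    populations: list[str]
    hierarchy: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci x 2"
            )
        if L == 0:
            raise ValueError("locus list is empty")
        if len(set(self.loci)) != L:
            raise ValueError("duplicate locus names")
        if len(self.populations) != n:
            raise ValueError("one population id per individual required")
        a1, a2 = self.calls[..., 0], self.calls[..., 1]
        miss1, miss2 = a1 == MISSING, a2 == MISSING
        if np.any(miss1 != miss2):
            raise ValueError("half-missing call: a call is both-present or MISSING")
        if np.any((~miss1) & ((a1 <= 0) | (a2 <= 0))):
            raise ValueError("allele codes must be positive integers")

    # -- basic structure -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_ids(self) -> list[str]:
        """Population ids in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def indices_of(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations, dtype=object) == population)
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)`` mask of MISSING calls."""
        return self.calls[..., 0] == MISSING

    def calls_at(self, locus: str, population: str) -> np.ndarray:
        """Non-missing calls (k, 2) for one locus in one population."""
        li = self.locus_index(locus)
        sub = self.calls[self.indices_of(population), li, :]
        return sub[sub[:, 0] != MISSING]

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeTable(
            individuals=list(self.individuals),
            loci=list(loci),
            calls=self.calls[:, idx, :].copy(),
            populations=list(self.populations),
            hierarchy=dict(self.hierarchy),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.populations == other.populations
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Genepop format
# ---------------------------------------------------------------------------

def _infer_digits(fields: list[str]) -> int:
    widths = {len(f) for f in fields if f}
    for d in (2, 3):
        if widths <= {2 * d}:
            return d
    raise GenotypeParseError(
        f"cannot infer allele digit width from genotype fields of widths {sorted(widths)}"
    )


def read_genepop(path: str | Path, digits: int | None = None,
                 pop_names: Sequence[str] | None = None) -> GenotypeTable:
    """Read a Genepop text file (2- or 3-digit alleles).

    The file is: a title line, one locus name per line (or a single
    comma-separated line), then ``POP`` blocks of ``id , g1 g2 ...`` rows where
    each genotype field is two fixed-width allele codes and ``0`` means
    missing.  Populations are named after the id of the *last* individual in
    each block (Genepop convention); duplicates get a numeric suffix.
    ``pop_names`` overrides the convention with an explicit sidecar list, one
    name per POP block.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise GenotypeParseError(f"{path}: not a Genepop file (too short)")
    it = iter(enumerate(lines[1:], start=2))

    loci: list[str] = []
    pop_line_seen = False
    for lineno, raw in it:
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_line_seen = True
            break
        if "," in line:
            loci.extend(tok.strip() for tok in line.split(",") if tok.strip())
        else:
            loci.append(line)
    if not pop_line_seen:
        raise GenotypeParseError(f"{path}: no POP separator found")
    if not loci:
        raise GenotypeParseError(f"{path}: no locus names before first POP")

    blocks: list[list[tuple[str, list[str]]]] = [[]]
    for lineno, raw in it:
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            blocks.append([])
            continue
        if "," not in line:
            raise GenotypeParseError(f"{path}:{lineno}: expected 'id , genotypes' row")
        ind_id, _, rest = line.partition(",")
        fields = rest.split()
        if len(fields) != len(loci):
            raise GenotypeParseError(
                f"{path}:{lineno}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        blocks[-1].append((ind_id.strip(), fields))

    blocks = [b for b in blocks if b]
    if not blocks:
        raise GenotypeParseError(f"{path}: no individuals")

    if digits is None:
        digits = _infer_digits([f for b in blocks for _, fs in b for f in fs])
    if pop_names is not None and len(pop_names) != len(blocks):
        raise GenotypeParseError(
            f"{path}: {len(pop_names)} pop_names for {len(blocks)} POP blocks"
        )

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[np.ndarray] = []
    pop_names_used: set[str] = set()
    for bi, block in enumerate(blocks):
        pop_name = pop_names[bi] if pop_names is not None else block[-1][0]
        if pop_name in pop_names_used:
            pop_name = f"{pop_name}_{len(pop_names_used) + 1}"
        pop_names_used.add(pop_name)
        for ind_id, fields in block:
            row = np.empty((len(loci), 2), dtype=np.int32)
            for li, f in enumerate(fields):
                if len(f) != 2 * digits or not f.isdigit():
                    raise GenotypeParseError(
                        f"{path}: bad genotype field {f!r} for individual "
                        f"{ind_id!r} (expected {2 * digits} digits)"
                    )
                a1, a2 = int(f[:digits]), int(f[digits:])
                if a1 == 0 or a2 == 0:
                    row[li] = (MISSING, MISSING)
                else:
                    row[li] = (a1, a2)
            individuals.append(ind_id)
            populations.append(pop_name)
            rows.append(row)

    return GenotypeTable(
        individuals=individuals,
        loci=loci,
        calls=np.stack(rows),
        populations=populations,
    )


def write_genepop(gt: GenotypeTable, path: str | Path, digits: int | None = None,
                  title: str = "landgen export") -> None:
    """Write a :class:`GenotypeTable` in Genepop format (missing -> 00/000)."""
    max_allele = int(gt.calls.max(initial=0))
    if digits is None:
        digits = 2 if max_allele < 100 else 3
    if max_allele >= 10 ** digits:
        raise ValueError(f"allele code {max_allele} does not fit in {digits} digits")
    out = [title]
    out.extend(gt.loci)
    pop_ids = gt.population_ids()
    for pop in pop_ids:
        out.append("POP")
        for i in gt.indices_of(pop):
            fields = []
            for li in range(gt.n_loci):
                a1, a2 = gt.calls[i, li]
                if a1 == MISSING:
                    a1 = a2 = 0
                fields.append(f"{a1:0{digits}d}{a2:0{digits}d}")
            out.append(f"{gt.individuals[i]} , " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Long-form CSV: individual, population, locus, allele1, allele2
# ---------------------------------------------------------------------------

def read_long_csv(path: str | Path) -> GenotypeTable:
    """Read the long-form dialect: one row per call, 0/empty = missing."""
    df = pd.read_csv(path, dtype={"individual": str, "population": str, "locus": str})
    required = {"individual", "population", "locus", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise GenotypeParseError(f"{path}: long CSV needs columns {sorted(required)}")
    loci = list(dict.fromkeys(df["locus"]))
    ind_pop: dict[str, str] = {}
    for ind, pop in zip(df["individual"], df["population"]):
        if ind_pop.setdefault(ind, pop) != pop:
            raise GenotypeParseError(f"{path}: individual {ind!r} in two populations")
    individuals = list(ind_pop)
    calls = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int32)
    ind_ix = {v: i for i, v in enumerate(individuals)}
    loc_ix = {v: i for i, v in enumerate(loci)}
    a1 = df["allele1"].fillna(0).astype(int).to_numpy()
    a2 = df["allele2"].fillna(0).astype(int).to_numpy()
    for ind, loc, x, y in zip(df["individual"], df["locus"], a1, a2):
        if x > 0 and y > 0:
            calls[ind_ix[ind], loc_ix[loc]] = (x, y)
    return GenotypeTable(
        individuals=individuals,
        loci=loci,
        calls=calls,
        populations=[ind_pop[i] for i in individuals],
    )


def write_long_csv(gt: GenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "population", "locus", "allele1", "allele2"])
        for i, (ind, pop) in enumerate(zip(gt.individuals, gt.populations)):
            for li, loc in enumerate(gt.loci):
                a1, a2 = gt.calls[i, li]
                if a1 == MISSING:
                    a1 = a2 = 0
                w.writerow([ind, pop, loc, int(a1), int(a2)])


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(?P<deg>\d+(?:[.,]\d+)?)\s*[°º]\s*
         (?:(?P<min>\d+(?:[.,]\d+)?)\s*[′'´]\s*)?
         (?:(?P<sec>\d+(?:[.,]\d+)?)\s*[″"]\s*)?
         (?P<hem>[NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def parse_dms(token: str | float) -> float:
    """Parse a coordinate as decimal degrees.

    Accepts plain decimals (dot or comma decimal mark) and DMS strings such as
    ``40°51′2.11″N`` or ``3°57′24,02″W``.  South and West hemispheres are
    negative.
    """
    if isinstance(token, (int, float)) and not isinstance(token, bool):
        return float(token)
    s = str(token).strip()
    plain = s.replace(",", ".")
    try:
        return float(plain)
    except ValueError:
        pass
    m = _DMS_RE.match(s)
    if not m:
        raise ValueError(f"unparseable coordinate {token!r}")
    to_f = lambda x: float(x.replace(",", ".")) if x else 0.0  # noqa: E731
    value = to_f(m["deg"]) + to_f(m["min"]) / 60.0 + to_f(m["sec"]) / 3600.0
    if m["hem"] and m["hem"].upper() in "SW":
        value = -value
    return value


@dataclass
class SiteTable:
    """Per-population geography and climate.

    Backed by a :class:`pandas.DataFrame` indexed by population id with
    columns ``lat``, ``lon`` (decimal degrees), ``elevation`` (m), ``tmax``,
    ``tmin`` (deg C), ``mountain_range`` and ``env_class``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("population ids must be unique")
        for col in ("lat", "lon"):
            if col not in df.columns:
                raise ValueError(f"site table misses column {col!r}")
        if not ((df["lat"].abs() <= 90).all() and (df["lon"].abs() <= 180).all()):
            raise ValueError("coordinates outside [-90,90] x [-180,180]")

    @property
    def populations(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lat, lon)."""
        return self.data[["lat", "lon"]].to_numpy(dtype=float)

    def hierarchy(self) -> dict[str, tuple[str, str]]:
        return {
            p: (str(r.get("mountain_range", "")), str(r.get("env_class", "")))
            for p, r in self.data.iterrows()
        }

    def reindex(self, populations: Sequence[str]) -> "SiteTable":
        missing = set(populations) - set(self.data.index)
        if missing:
            raise KeyError(f"site table misses populations {sorted(missing)}")
        return SiteTable(self.data.loc[list(populations)].copy())


_COL_ALIASES: Mapping[str, str] = {
    "pop_id": "population", "pop": "population", "id": "population",
    "lat.": "lat", "latitude": "lat", "long.": "lon", "long": "lon",
    "longitude": "lon", "elevation_m": "elevation", "elevation (m)": "elevation",
    "tmax_c": "tmax", "tmin_c": "tmin", "tmax (c)": "tmax", "tmin (c)": "tmin",
    "env. class.": "env_class", "env_class.": "env_class",
    "environment": "env_class", "mountain": "mountain_range",
}


def read_site_table(path: str | Path) -> SiteTable:
    """Read a delimited site table; DMS or decimal coordinates, ','/'.'/tab ok."""
    text = Path(path).read_text(encoding="utf-8")
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=delim, dtype=str)
    df.columns = [_COL_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    if "population" not in df.columns:
        raise ValueError(f"{path}: no population id column")
    out = pd.DataFrame(index=pd.Index(df["population"].str.strip(), name="population"))
    out["lat"] = [parse_dms(v) for v in df["lat"]]
    out["lon"] = [parse_dms(v) for v in df["lon"]]
    for col in ("elevation", "tmax", "tmin"):
        if col in df.columns:
            out[col] = [float(str(v).replace(",", ".")) for v in df[col]]
    for col in ("mountain_range", "env_class", "name"):
        if col in df.columns:
            out[col] = df[col].str.strip().to_numpy()
    if "env_class" in out.columns:
        out["env_class"] = out["env_class"].str.lower()
    return SiteTable(out)


def _data_path(name: str) -> Path:
    return Path(__file__).with_name("data") / name


def load_packaged_sites() -> SiteTable:
    """The packaged nine-population Sistema Central site table.

    Nine Silene ciliata populations in three Iberian mountain ranges
    (Guadarrama, Gredos, Bejar), three per range along an elevational
    gradient, with annual temperature extremes and habitat-quality class.
    """
    return read_site_table(_data_path("sistema_central_sites.csv"))


def load_packaged_diversity() -> pd.DataFrame:
    """Published per-population diversity summaries for the packaged sites.

    Columns: n, Na, PA, A, Ho, He, Fis — indexed by population id, aligned
    with :func:`load_packaged_sites`.  Used by the worked spatial-model
    example (diversity against minimum temperature).
    """
    df = pd.read_csv(_data_path("sistema_central_diversity.csv"), index_col="population")
    return df


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    missingness: pd.Series          # per locus, fraction of MISSING calls
    sample_sizes: pd.Series         # per population, individuals
    monomorphic_loci: list[str]

    def __str__(self) -> str:
        lines = ["Per-locus missingness:"]
        lines += [f"  {k}: {v:.3f}" for k, v in self.missingness.items()]
        lines.append("Per-population sample size:")
        lines += [f"  {k}: {v}" for k, v in self.sample_sizes.items()]
        lines.append(f"Monomorphic loci: {', '.join(self.monomorphic_loci) or 'none'}")
        return "\n".join(lines)


def validate(gt: GenotypeTable) -> ValidationReport:
    """Data-quality report: missingness, sample sizes, monomorphic loci."""
    miss = gt.missing_mask()
    missingness = pd.Series(miss.mean(axis=0), index=gt.loci, name="missingness")
    sizes = pd.Series(gt.populations, dtype=object).value_counts(sort=False)
    sizes = sizes.reindex(gt.population_ids())
    mono = []
    for li, loc in enumerate(gt.loci):
        obs = gt.calls[~miss[:, li], li, :]
        if obs.size and np.unique(obs).size == 1:
            mono.append(loc)
    return ValidationReport(missingness, sizes, mono)
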