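"""Frequency-of-frequencies data model and I/O.

Repeated-counting capture-recapture data are summarized by the counts
``n_k`` = number of individuals observed exactly ``k`` times, for
``k >= 1``.  The zero class ``n_0`` (never-observed individuals) is by
construction unobservable and is never stored here; estimating it is the
whole point of the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountFrequencies",
    "frequencies_from_counts",
    "load_frequencies",
    "load_fixture",
    "write_frequencies",
    "FIXTURES",
]

#: Named datasets shipped with the package (observed capture-count
#: frequency tables from the published case studies: street prostitutes in
#: Vancouver 1986/87, opiate users in Rotterdam 1994, heroin users in
#: Bangkok 2002).
FIXTURES = ("vancouver", "rotterdam", "bangkok")


@dataclass(frozen=True)
class CountFrequencies:
    """Zero-truncated frequency-of-frequencies table.

    Parameters
    ----------
    freqs
        Mapping ``k -> n_k`` for positive counts ``k``.  Entries with
        ``n_k == 0`` are dropped on construction; missing ``k`` between 1
        and ``kmax`` are implicit zeros.

    Attributes
    ----------
    n : int
        Total number of observed individuals, ``sum(n_k)``.
    s : int
        Total number of captures, ``sum(k * n_k)``.
    kmax : int
        Largest observed capture count.
    """

    freqs: Mapping[int, int]
    n: int = field(init=False)
    s: int = field(init=False)
    kmax: int = field(init=False)

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for k, nk in sorted(self.freqs.items()):
            k = _as_int(k, "count")
            nk = _as_int(nk, "frequency")
            if k < 1:
                raise ValueError(f"capture counts must be >= 1, got k={k}")
            if nk < 0:
                raise ValueError(f"negative frequency n_{k}={nk}")
            if nk > 0:
                clean[k] = nk
        if not clean:
            raise ValueError("no individuals: all frequencies are zero or missing")
        object.__setattr__(self, "freqs", clean)
        object.__setattr__(self, "n", sum(clean.values()))
        object.__setattr__(self, "s", sum(k * v for k, v in clean.items()))
        object.__setattr__(self, "kmax", max(clean))

    # -- accessors -------------------------------------------------------

    def __getitem__(self, k: int) -> int:
        return self.freqs.get(k, 0)

    @property
    def n1(self) -> int:
        """Number of singletons (individuals captured exactly once)."""
        return self[1]

    @property
    def tail_count(self) -> int:
        """Number of individuals captured more than once, ``sum_{k>1} n_k``."""
        return self.n - self.n1

    def dense(self) -> np.ndarray:
        """Frequencies as an integer array indexed by count, 0..kmax.

        Index 0 is always 0: the zero class is not part of the data.
        """
        out = np.zeros(self.kmax + 1, dtype=np.int64)
        for k, nk in self.freqs.items():
            out[k] = nk
        return out

    def to_counts(self) -> np.ndarray:
        """Expand back to a sorted vector of per-individual counts."""
        return np.repeat(
            np.fromiter(self.freqs.keys(), dtype=np.int64),
            np.fromiter(self.freqs.values(), dtype=np.int64),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountFrequencies(n={self.n}, s={self.s}, kmax={self.kmax})"


def _as_int(x, what: str) -> int:
    if isinstance(x, (bool, float, np.floating)) and float(x) != int(x):
        raise ValueError(f"{what} must be an integer, got {x!r}")
    try:
        return int(x)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{what} must be an integer, got {x!r}") from exc


def frequencies_from_counts(
    counts: Iterable[int], *, drop_zeros: bool = False
) -> CountFrequencies:
    """Tabulate per-individual capture counts into a frequency table.

    Observed capture-recapture data cannot contain zeros, so zero entries
    raise by default; ``drop_zeros=True`` enables truncation, which is
    what the simulator uses to discard the latent zero class.
    """
    freqs: dict[int, int] = {}
    for i, c in enumerate(counts):
        try:
            c = _as_int(c, "capture count")
        except ValueError as exc:
            raise ValueError(f"entry {i}: {exc}") from None
        if c < 0:
            raise ValueError(f"entry {i}: negative capture count {c}")
        if c == 0:
            if drop_zeros:
                continue
            raise ValueError(
                f"entry {i}: zero capture count in observed data "
                "(pass drop_zeros=True to truncate simulator output)"
            )
        freqs[c] = freqs.get(c, 0) + 1
    if not freqs:
        raise ValueError("no positive counts in input")
    return CountFrequencies(freqs)


def load_frequencies(source: str | Path) -> CountFrequencies:
    """Read a two-column ``count<sep>frequency`` table.

    ``source`` may be a path or the table text itself.  The separator is
    auto-detected among tab, comma, and whitespace; a single header row is
    allowed.  Duplicate count rows are an error.
    """
    text = _read_source(source)
    rows = [ln.strip() for ln in text.splitlines()]
    rows = [r for r in rows if r and not r.startswith("#")]
    if not rows:
        raise ValueError("empty frequency table")
    sep = "," if "," in rows[0] else None  # None: any whitespace incl. tab
    df = pd.read_csv(
        io.StringIO("\n".join(rows)),
        sep=sep if sep else r"\s+",
        header=None,
        comment="#",
        skiprows=1 if _looks_like_header(rows[0], sep) else 0,
        dtype=str,
    )
    if df.shape[1] != 2:
        raise ValueError(f"expected two columns 'count frequency', got {df.shape[1]}")
    freqs: dict[int, int] = {}
    for _, (k_raw, nk_raw) in df.iterrows():
        k = _as_int(_numeric(k_raw, "count"), "count")
        nk = _as_int(_numeric(nk_raw, "frequency"), "frequency")
        if k in freqs:
            raise ValueError(f"duplicate row for count k={k}")
        if nk < 0:
            raise ValueError(f"negative frequency n_{k}={nk}")
        freqs[k] = nk
    return CountFrequencies(freqs)


def load_fixture(name: str) -> CountFrequencies:
    """Load one of the packaged case-study datasets by name."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    text = resources.files("oneinflate.data").joinpath(f"{name}.tsv").read_text()
    return load_frequencies(text)


def write_frequencies(data: CountFrequencies, path: str | Path | None = None) -> str:
    """Serialize to a dense two-column TSV (implicit zeros written out)."""
    lines = ["count\tfrequency"]
    lines += [f"{k}\t{data[k]}" for k in range(1, data.kmax + 1)]
    out = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(out)
    return out


def _read_source(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if not source.strip():
        raise ValueError("empty frequency table")
    if "\n" not in source and Path(source).is_file():
        return Path(source).read_text()
    if "\n" not in source:
        raise FileNotFoundError(f"no such frequency file: {source}")
    return source


def _numeric(x: str, what: str):
    try:
        return float(x)
    except ValueError:
        raise ValueError(f"{what} column contains non-numeric value {x!r}") from None


def _looks_like_header(row: str, sep: str | None) -> bool:
    parts = row.split(sep) if sep else row.split()
    for p in parts:
        try:
            float(p)
        except ValueError:
            return True
    return False
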