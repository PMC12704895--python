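"""Split-pool barcode architecture.

A cell acquires one well-specific barcode per round of split-pool
barcoding: the first during reverse transcription (round 0, the RT
round), subsequent ones by ligation.  A cell's identity is the ordered
tuple of wells it visited (:class:`WellPath`), and the sequencing read
covering the barcode side of the molecule carries, in order, a constant
adapter stem, the UMI, and the per-round barcodes separated by the
constant single-stranded linkers ("protrusions") that template each
ligation.  Because ligation stacks new adapters onto the outside of the
molecule, the *last* ligation round is sequenced first and the RT
barcode last; :func:`read_layout` encodes those coordinates once, and
both the read simulator and the demultiplexer consume them, so the two
can never disagree about where a barcode lives.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "BASES",
    "SchemeError",
    "InvalidWellPathError",
    "RoundSpec",
    "BarcodeScheme",
    "SegmentLayout",
    "WellPath",
    "combination_count",
    "read_layout",
    "assemble_construct",
    "validate_whitelists",
    "WhitelistReport",
    "hamming",
    "min_pairwise_hamming",
    "random_whitelist",
    "default_scheme",
    "truncation_window",
    "FRAMESHIFT_DELETION_LEN",
    "load_scheme",
    "save_scheme",
]

BASES = "ACGT"
_DNA_RE = re.compile(r"^[ACGT]*$")

#: Constant adapter stem preceding the UMI in the barcode read
#: (28 nt, the stem of the outermost ligation adapter).
DEFAULT_CONSTANT_PREFIX = "TATAGAATTCGCGGCCGCTCGCGATAGC"

#: Constant 8-nt single-stranded protrusion templating each ligation.
DEFAULT_LINKER = "ATCCTCCT"

#: Anchored oligo-dT stretch of the RT primer, downstream of the RT
#: barcode and upstream of the cDNA insert in the assembled construct.
DEFAULT_RT_SPACER = "T" * 16


class SchemeError(ValueError):
    """Invalid barcode-scheme configuration."""


class InvalidWellPathError(SchemeError):
    """A well index is out of range for its round."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class RoundSpec:
    """One round of split-pool barcoding.

    Parameters
    ----------
    round_index
        Ordinal of the round; 0 is the RT round.
    whitelist
        The valid well barcodes for this round, one per well, all the
        same length and unique.
    linker
        Constant linker ligated after this round's barcode (empty for
        schemes/rounds without one).
    """

    round_index: int
    whitelist: tuple[str, ...]
    linker: str = DEFAULT_LINKER

    def __post_init__(self) -> None:
        wl = tuple(self.whitelist)
        object.__setattr__(self, "whitelist", wl)
        if not wl:
            raise SchemeError(f"round {self.round_index}: empty whitelist")
        lengths = {len(b) for b in wl}
        if len(lengths) != 1:
            raise SchemeError(
                f"round {self.round_index}: whitelist entries of mixed length {sorted(lengths)}"
            )
        if len(set(wl)) != len(wl):
            dupes = sorted({b for b in wl if wl.count(b) > 1})
            raise SchemeError(f"round {self.round_index}: duplicate whitelist entries {dupes}")
        for b in wl:
            if not _DNA_RE.fullmatch(b):
                raise SchemeError(f"round {self.round_index}: non-ACGT barcode {b!r}")
        if not _DNA_RE.fullmatch(self.linker):
            raise SchemeError(f"round {self.round_index}: non-ACGT linker {self.linker!r}")

    @property
    def n_wells(self) -> int:
        return len(self.whitelist)

    @property
    def barcode_len(self) -> int:
        return len(self.whitelist[0])

    @property
    def linker_len(self) -> int:
        return len(self.linker)


@dataclass(frozen=True)
class BarcodeScheme:
    """The full combinatorial design shared by simulator and demultiplexer.

    ``rounds`` are listed in barcoding order (index 0 = RT).  When
    ``ligation_first`` is true (default) the read presents rounds in
    reverse barcoding order, matching the stacked-ligation geometry.
    For 4-round designs whose barcodes span two reads,
    ``n_reads_for_barcodes = 2`` and ``read2_rounds`` gives how many
    read-order rounds fall in the first barcode read; the layout is a
    single concatenated coordinate space over both reads.
    """

    rounds: tuple[RoundSpec, ...]
    umi_len: int = 8
    cdna_len: int = 50
    constant_prefix: str = DEFAULT_CONSTANT_PREFIX
    rt_spacer: str = DEFAULT_RT_SPACER
    n_reads_for_barcodes: int = 1
    read2_rounds: int | None = None
    ligation_first: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "rounds", tuple(self.rounds))
        if not 2 <= len(self.rounds) <= 4:
            raise SchemeError(f"need 2-4 rounds, got {len(self.rounds)}")
        for expected, rs in enumerate(self.rounds):
            if rs.round_index != expected:
                raise SchemeError(
                    f"rounds must be listed in barcoding order; found round_index "
                    f"{rs.round_index} at position {expected}"
                )
        if self.umi_len < 0:
            raise SchemeError("umi_len must be >= 0")
        if self.cdna_len < 1:
            raise SchemeError("cdna_len must be >= 1")
        if not _DNA_RE.fullmatch(self.constant_prefix):
            raise SchemeError("constant_prefix must be ACGT-only")
        if not _DNA_RE.fullmatch(self.rt_spacer):
            raise SchemeError("rt_spacer must be ACGT-only")
        if self.n_reads_for_barcodes not in (1, 2):
            raise SchemeError("n_reads_for_barcodes must be 1 or 2")
        if self.n_reads_for_barcodes == 2:
            if self.read2_rounds is None or not 1 <= self.read2_rounds < len(self.rounds):
                raise SchemeError("read2_rounds must be in [1, n_rounds) for two-read designs")

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def read_order(self) -> tuple[RoundSpec, ...]:
        """Rounds in the order they appear along the barcode read."""
        return tuple(reversed(self.rounds)) if self.ligation_first else self.rounds

    def combination_count(self) -> int:
        return combination_count(self)

    def layout(self) -> "SegmentLayout":
        return read_layout(self)


@dataclass(frozen=True)
class SegmentLayout:
    """Named, contiguous 0-based half-open coordinates within the barcode read(s).

    Segment names: ``constant``, ``umi``, ``bc_<round_index>`` and
    ``linker_<round_index>`` (the linker following that round's barcode
    in the read).  ``read_split`` is the coordinate where the second
    barcode read begins for two-read designs, else ``None``.
    """

    segments: tuple[tuple[str, int, int], ...]
    read_split: int | None = None

    def __post_init__(self) -> None:
        pos = 0
        for name, start, end in self.segments:
            if start != pos or end < start:
                raise SchemeError(f"layout segments must tile contiguously; bad segment {name}")
            pos = end

    @property
    def span(self) -> int:
        return self.segments[-1][2] if self.segments else 0

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.segments)

    def coords(self, name: str) -> tuple[int, int]:
        for n, s, e in self.segments:
            if n == name:
                return s, e
        raise KeyError(name)

    def barcode_segments(self) -> tuple[tuple[str, int, int], ...]:
        return tuple(seg for seg in self.segments if seg[0].startswith("bc_"))

    def linker_segments(self) -> tuple[tuple[str, int, int], ...]:
        return tuple(seg for seg in self.segments if seg[0].startswith("linker_"))


@dataclass(frozen=True)
class WellPath:
    """One well index per round, in barcoding order (round 0 first)."""

    wells: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(int(w) for w in self.wells))

    def __iter__(self):
        return iter(self.wells)

    def __len__(self) -> int:
        return len(self.wells)

    def __getitem__(self, i: int) -> int:
        return self.wells[i]

    def serialize(self) -> str:
        return "-".join(str(w) for w in self.wells)

    @classmethod
    def deserialize(cls, s: str) -> "WellPath":
        return cls(tuple(int(x) for x in s.split("-")))

    def validate(self, scheme: BarcodeScheme) -> None:
        if len(self.wells) != scheme.n_rounds:
            raise InvalidWellPathError(
                f"path has {len(self.wells)} wells for a {scheme.n_rounds}-round scheme"
            )
        for rs, w in zip(scheme.rounds, self.wells):
            if not 0 <= w < rs.n_wells:
                raise InvalidWellPathError(
                    f"well {w} out of range for round {rs.round_index} ({rs.n_wells} wells)"
                )


def combination_count(scheme: BarcodeScheme) -> int:
    """Size of the combination space: the product of wells over rounds."""
    return math.prod(rs.n_wells for rs in scheme.rounds)


def read_layout(scheme: BarcodeScheme) -> SegmentLayout:
    """Deterministic coordinates of every segment of the barcode read(s).

    Order along the read: constant prefix, UMI, then for each round in
    read order its barcode followed by its linker — except the last
    round, whose barcode ends the barcode span (no trailing linker).
    """
    segs: list[tuple[str, int, int]] = []
    pos = 0

    def push(name: str, length: int) -> None:
        nonlocal pos
        segs.append((name, pos, pos + length))
        pos += length

    if scheme.constant_prefix:
        push("constant", len(scheme.constant_prefix))
    if scheme.umi_len:
        push("umi", scheme.umi_len)
    order = scheme.read_order
    split_coord: int | None = None
    for i, rs in enumerate(order):
        push(f"bc_{rs.round_index}", rs.barcode_len)
        last = i == len(order) - 1
        if not last and rs.linker:
            push(f"linker_{rs.round_index}", rs.linker_len)
        if scheme.n_reads_for_barcodes == 2 and i == scheme.read2_rounds - 1:
            split_coord = pos
    return SegmentLayout(tuple(segs), read_split=split_coord)


def assemble_construct(
    scheme: BarcodeScheme, path: WellPath | Sequence[int], umi: str, insert: str
) -> str:
    """In-silico assembly of one fully barcoded cDNA molecule.

    Returns ``constant_prefix + umi + (bc + linker per read-order
    round, last barcode bare) + rt_spacer + insert``.  The leading
    ``read_layout(scheme).span`` bases are exactly what the barcode
    read sequences.
    """
    if not isinstance(path, WellPath):
        path = WellPath(tuple(path))
    path.validate(scheme)
    if len(umi) != scheme.umi_len:
        raise SchemeError(f"umi length {len(umi)} != scheme umi_len {scheme.umi_len}")
    if not insert:
        raise SchemeError("insert must be non-empty")
    parts = [scheme.constant_prefix, umi]
    order = scheme.read_order
    for i, rs in enumerate(order):
        parts.append(rs.whitelist[path[rs.round_index]])
        if i < len(order) - 1:
            parts.append(rs.linker)
    parts.append(scheme.rt_spacer)
    parts.append(insert)
    return "".join(parts)


def min_pairwise_hamming(whitelist: Sequence[str]) -> int:
    """Brute-force minimum pairwise Hamming distance (whitelists are small)."""
    if len(whitelist) < 2:
        return len(whitelist[0]) if whitelist else 0
    return min(hamming(a, b) for a, b in itertools.combinations(whitelist, 2))


@dataclass(frozen=True)
class WhitelistReport:
    per_round_min_hamming: tuple[int, ...]
    per_round_duplicates: tuple[tuple[str, ...], ...]
    required_min_hamming: int

    @property
    def ok(self) -> bool:
        return all(not d for d in self.per_round_duplicates) and all(
            m >= self.required_min_hamming for m in self.per_round_min_hamming
        )


def validate_whitelists(
    scheme_or_lists: BarcodeScheme | Sequence[Sequence[str]],
    min_pairwise_hamming_required: int = 1,
) -> WhitelistReport:
    """Audit whitelists: duplicates are a hard error, distances are reported."""
    if isinstance(scheme_or_lists, BarcodeScheme):
        lists: list[Sequence[str]] = [rs.whitelist for rs in scheme_or_lists.rounds]
    else:
        lists = list(scheme_or_lists)
    mins: list[int] = []
    dupes: list[tuple[str, ...]] = []
    for r, wl in enumerate(lists):
        wl = list(wl)
        seen: set[str] = set()
        d = sorted({b for b in wl if b in seen or seen.add(b)})  # type: ignore[func-returns-value]
        if d:
            raise SchemeError(f"round {r}: duplicate whitelist entries {d}")
        dupes.append(tuple(d))
        mins.append(min_pairwise_hamming(wl))
    return WhitelistReport(tuple(mins), tuple(dupes), min_pairwise_hamming_required)


def random_whitelist(
    n: int,
    length: int,
    seed: int,
    min_hamming: int = 1,
    exclude: Iterable[str] = (),
    max_tries: int = 200_000,
) -> tuple[str, ...]:
    """Greedy seeded whitelist with an enforced minimum pairwise distance.

    ``exclude`` lists forbidden sequences (e.g. substrings of the
    constant linkers, so a frame-shifted constant region can never
    masquerade as a valid well barcode).  Raises if the requested code
    cannot be assembled (e.g. sizes beyond the Singleton bound
    ``4**(length - min_hamming + 1)``).
    """
    import numpy as np

    if n > 4 ** (length - min_hamming + 1):
        raise SchemeError(
            f"{n} barcodes of length {length} at min distance {min_hamming} "
            f"exceed the Singleton bound {4 ** (length - min_hamming + 1)}"
        )
    forbidden = set(exclude)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for _ in range(max_tries):
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if cand in forbidden:
            continue
        if all(hamming(cand, c) >= min_hamming for c in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                return tuple(chosen)
    raise SchemeError(
        f"could not assemble {n} barcodes of length {length} at min distance "
        f"{min_hamming} within {max_tries} draws"
    )


def default_scheme(
    n_rounds: int = 3,
    n_wells: int = 96,
    barcode_len: int = 4,
    umi_len: int = 8,
    cdna_len: int = 50,
    linker: str = DEFAULT_LINKER,
    whitelist_seed: int = 7000,
) -> BarcodeScheme:
    """The reference 3-round/96-well design with generated whitelists.

    Whitelists are deterministic in ``whitelist_seed`` (one sub-seed per
    round) so simulator and demultiplexer built independently from the
    same call agree byte-for-byte.  Barcodes equal to a substring of the
    constant regions (prefix, linker, RT spacer) are excluded so a
    frame-shifted constant region cannot masquerade as a valid well.
    """
    constants = DEFAULT_CONSTANT_PREFIX + linker + DEFAULT_RT_SPACER + linker
    exclude = {
        constants[i : i + barcode_len]
        for i in range(len(constants) - barcode_len + 1)
    }
    rounds = tuple(
        RoundSpec(
            round_index=r,
            whitelist=random_whitelist(
                n_wells, barcode_len, seed=whitelist_seed + r, exclude=exclude
            ),
            linker=linker,
        )
        for r in range(n_rounds)
    )
    kwargs = {}
    if n_rounds == 4:
        kwargs = dict(n_reads_for_barcodes=2, read2_rounds=2)
    return BarcodeScheme(rounds=rounds, umi_len=umi_len, cdna_len=cdna_len, **kwargs)


def truncation_window(
    scheme: BarcodeScheme, linker_name: str | None = None
) -> tuple[int, int]:
    """9-nt window of the two candidate 8-nt frameshift deletions.

    The deletion removes one 8-nt linker starting at either of two
    adjacent positions, so the affected window spans the linker plus one
    base (linker start .. linker end + 1).  Default linker: the first
    linker along the read (between the last two ligation rounds, the
    mid-read window where truncations are diagnosed).
    """
    layout = read_layout(scheme)
    linkers = layout.linker_segments()
    if not linkers:
        raise SchemeError("scheme has no linker segments; no frameshift window defined")
    if linker_name is None:
        name, start, end = linkers[0]
    else:
        start, end = layout.coords(linker_name)
    if end - start != 8:
        raise SchemeError("frameshift model assumes an 8-nt linker")
    return start, end + 1


#: Length of the frameshift deletion (one linker).
FRAMESHIFT_DELETION_LEN = 8


# ---------------------------------------------------------------------------
# YAML config I/O


def save_scheme(scheme: BarcodeScheme, path: str | Path) -> None:
    doc = {
        "umi_len": scheme.umi_len,
        "cdna_len": scheme.cdna_len,
        "constant_prefix": scheme.constant_prefix,
        "rt_spacer": scheme.rt_spacer,
        "n_reads_for_barcodes": scheme.n_reads_for_barcodes,
        "read2_rounds": scheme.read2_rounds,
        "ligation_first": scheme.ligation_first,
        "rounds": [
            {"linker": rs.linker, "whitelist": list(rs.whitelist)} for rs in scheme.rounds
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scheme(path: str | Path) -> BarcodeScheme:
    """Load a scheme from YAML; round whitelists may be inline lists or
    ``whitelist_file`` references (one barcode per line, relative to the
    config)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    rounds = []
    for r, rdoc in enumerate(doc["rounds"]):
        if "whitelist" in rdoc:
            wl = tuple(rdoc["whitelist"])
        else:
            wl_path = Path(rdoc["whitelist_file"])
            if not wl_path.is_absolute():
                wl_path = path.parent / wl_path
            if not wl_path.exists():
                raise SchemeError(f"whitelist file not found: {wl_path}")
            wl = tuple(
                line.strip() for line in wl_path.read_text().splitlines() if line.strip()
            )
        rounds.append(RoundSpec(round_index=r, whitelist=wl, linker=rdoc.get("linker", "")))
    return BarcodeScheme(
        rounds=tuple(rounds),
        umi_len=doc.get("umi_len", 8),
        cdna_len=doc.get("cdna_len", 50),
        constant_prefix=doc.get("constant_prefix", DEFAULT_CONSTANT_PREFIX),
        rt_spacer=doc.get("rt_spacer", DEFAULT_RT_SPACER),
        n_reads_for_barcodes=doc.get("n_reads_for_barcodes", 1),
        read2_rounds=doc.get("read2_rounds"),
        ligation_first=doc.get("ligation_first", True),
    )
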