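"""Genetic-code tables and translation.

Three tables ship with the package as plain-text key-value files:

``bact11``
    The standard bacterial code: stops {TAA, TAG, TGA}, starts
    {ATG, GTG, TTG}.
``pyl_readthrough``
    Identical to ``bact11`` except TAG is a readthrough codon emitting
    pyrrolysine (``O``) instead of terminating.
``sec_readthrough``
    Identical to ``bact11`` except TGA emits selenocysteine (``U``).

Every table must partition the 64 codons into coding, stop and readthrough
roles; this is asserted at load time.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

from .sequences import NucleotideSequence, ProteinSequence, revcomp_str

logger = logging.getLogger("gcescan.codes")

ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]

StopPolicy = Literal["truncate", "error", "trailing_star"]

FRAME_IDS = ("+1", "+2", "+3", "-1", "-2", "-3")


class PrematureStopError(ValueError):
    """Raised by :func:`translate` under ``stop_policy='error'``."""


class TableIntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticCodeTable:
    """Codon map with per-codon stop/readthrough semantics and start codons."""

    name: str
    codon_map: dict  # sense codon -> residue symbol
    stops: frozenset
    readthrough: dict  # codon -> noncanonical residue symbol
    starts: frozenset

    def __post_init__(self) -> None:
        roles = list(self.codon_map) + list(self.stops) + list(self.readthrough)
        if sorted(roles) != sorted(ALL_CODONS):
            raise TableIntegrityError(
                f"table {self.name!r} does not partition the 64 codons: "
                f"{len(self.codon_map)} coding, {len(self.stops)} stop, "
                f"{len(self.readthrough)} readthrough"
            )
        if set(self.stops) & set(self.readthrough):
            raise TableIntegrityError("stop and readthrough codon sets overlap")

    def residue(self, codon: str) -> str:
        """Residue for a sense or readthrough codon ('X' if codon holds N)."""
        if "N" in codon:
            return "X"
        if codon in self.readthrough:
            return self.readthrough[codon]
        return self.codon_map[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_text(cls, text: str) -> "GeneticCodeTable":
        name = ""
        codon_map: dict = {}
        stops: set = set()
        readthrough: dict = {}
        starts: set = set()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            key = parts[0]
            if key == "name":
                name = parts[1]
            elif key == "start":
                starts.add(parts[1])
            elif key == "stop":
                stops.add(parts[1])
            elif key == "readthrough":
                readthrough[parts[1]] = parts[2]
            elif key == "codon":
                codon_map[parts[1]] = parts[2]
            else:
                raise ValueError(f"unknown table directive {key!r}")
        return cls(name=name, codon_map=codon_map, stops=frozenset(stops),
                   readthrough=readthrough, starts=frozenset(starts))

    def to_text(self) -> str:
        lines = [f"name {self.name}"]
        lines += [f"start {c}" for c in sorted(self.starts)]
        lines += [f"stop {c}" for c in sorted(self.stops)]
        lines += [f"readthrough {c} {r}" for c, r in sorted(self.readthrough.items())]
        lines += [f"codon {c} {self.codon_map[c]}" for c in sorted(self.codon_map)]
        return "\n".join(lines) + "\n"


def load_table(name: str) -> GeneticCodeTable:
    """Load a packaged table (``bact11``, ``pyl_readthrough``, ``sec_readthrough``)
    or read one from a file path."""
    pkg_file = resources.files("gcescan.data").joinpath(f"{name}.tab")
    if pkg_file.is_file():
        return GeneticCodeTable.from_text(pkg_file.read_text())
    path = Path(name)
    if path.is_file():
        return GeneticCodeTable.from_text(path.read_text())
    raise FileNotFoundError(f"no packaged or on-disk genetic-code table {name!r}")


def translate(s: NucleotideSequence, table: GeneticCodeTable,
              stop_policy: StopPolicy = "truncate") -> ProteinSequence:
    """Translate from offset 0.

    Readthrough codons emit their noncanonical residue and translation
    continues; a stop codon terminates per ``stop_policy``.  Codons containing
    ``N`` emit ``X``.  An incomplete trailing codon is ignored with a logged
    warning.
    """
    if len(s.seq) < 3:
        raise ValueError(f"sequence {s.id!r} shorter than one codon")
    residues: list[str] = []
    n_full = len(s.seq) // 3
    if len(s.seq) % 3:
        logger.warning("TRAILING_CODON seq=%s dropped %d nt", s.id, len(s.seq) % 3)
    for i in range(n_full):
        codon = s.seq[3 * i: 3 * i + 3]
        if table.is_stop(codon):
            if stop_policy == "error":
                raise PrematureStopError(
                    f"stop codon {codon} at codon index {i} in {s.id!r}"
                )
            if stop_policy == "trailing_star":
                residues.append("*")
            break
        residues.append(table.residue(codon))
    return ProteinSequence(id=s.id, seq="".join(residues), description=s.description)


def _frame_string(seq: str, table: GeneticCodeTable) -> str:
    """Full-frame translation with '*' at stop codons (no termination)."""
    out = []
    for i in range(len(seq) // 3):
        codon = seq[3 * i: 3 * i + 3]
        out.append("*" if table.is_stop(codon) else table.residue(codon))
    return "".join(out)


def six_frame_translate(
    s: NucleotideSequence, table: GeneticCodeTable
) -> list[tuple[str, list[ProteinSequence]]]:
    """Translate all six frames, splitting each frame's translation at stops.

    Frames ``+1/+2/+3`` read the forward strand at offsets 0/1/2; ``-1/-2/-3``
    read the reverse complement at offsets 0/1/2.  Joining a frame's fragments
    with ``'*'`` reconstructs that frame's full translation.
    """
    if len(s.seq) < 3:
        raise ValueError(f"sequence {s.id!r} shorter than one codon")
    frames = []
    rc = revcomp_str(s.seq)
    for frame_id in FRAME_IDS:
        strand_seq = s.seq if frame_id.startswith("+") else rc
        offset = int(frame_id[1]) - 1
        full = _frame_string(strand_seq[offset:], table)
        fragments = [
            ProteinSequence(id=f"{s.id}|{frame_id}|{k}", seq=frag)
            for k, frag in enumerate(full.split("*"))
            if frag
        ]
        frames.append((frame_id, fragments))
    return frames
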