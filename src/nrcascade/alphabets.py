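"""Reduced amino-acid alphabets.

An :class:`AlphabetMap` partitions the 20 standard residues into ordered,
named groups.  Two instances ship as defaults:

* ``CTF_ALPHABET`` — the seven-class partition used by the conjoint-triad
  encoding, grouping residues by side-chain dipole and volume:
  {AGV}, {ILFP}, {YMTS}, {HNQW}, {RK}, {DE}, {C}.
* ``CGR12_ALPHABET`` — a twelve-group conservative-substitution partition
  used to assign residues to the vertices of the 12-gon in the chaos-game
  encoder.  The twelve vertex groups are not uniquely fixed by the method's
  description, so this grouping is a documented default and any partition
  with twelve groups can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AlphabetMap:
    """An ordered partition of the 20 standard amino acids.

    Parameters
    ----------
    name:
        Identifier for the partition.
    groups:
        Ordered tuple of residue strings; groups must be pairwise disjoint
        and jointly cover the 20-letter alphabet.
    """

    name: str
    groups: tuple[str, ...]
    class_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for k, group in enumerate(self.groups, start=1):
            if not group:
                raise ConfigurationError(f"alphabet {self.name!r}: group {k} is empty")
            for residue in group:
                if residue not in STANDARD_AA:
                    raise ConfigurationError(
                        f"alphabet {self.name!r}: {residue!r} is not a standard residue"
                    )
                if residue in seen:
                    raise ConfigurationError(
                        f"alphabet {self.name!r}: residue {residue!r} appears in "
                        f"groups {seen[residue]} and {k}"
                    )
                seen[residue] = k
        missing = set(STANDARD_AA) - set(seen)
        if missing:
            raise ConfigurationError(
                f"alphabet {self.name!r}: residues {sorted(missing)} unassigned"
            )
        object.__setattr__(self, "class_of", seen)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def reduce(self, residues: str) -> list[int]:
        """Map a residue string to 1-based group indices.

        Raises :class:`~nrcascade.errors.SequenceDomainError` naming the
        first out-of-domain residue and its position.
        """
        from .errors import SequenceDomainError

        out = []
        for pos, r in enumerate(residues):
            try:
                out.append(self.class_of[r])
            except KeyError:
                raise SequenceDomainError(
                    f"residue {r!r} at position {pos} is outside alphabet {self.name!r}"
                ) from None
        return out

    def group_label(self, k: int) -> str:
        """Residue-string label of 1-based group ``k`` (e.g. ``'AGV'``)."""
        return self.groups[k - 1]


#: Seven-class partition by side-chain dipole and volume.
CTF_ALPHABET = AlphabetMap(
    name="ctf7",
    groups=("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"),
)

#: Default 12-group partition for the chaos-game 12-gon vertices.
CGR12_ALPHABET = AlphabetMap(
    name="cgr12",
    groups=("A", "G", "P", "C", "ST", "DE", "NQ", "H", "KR", "M", "ILV", "FYW"),
)


def load_alphabet(path, name: str | None = None) -> AlphabetMap:
    """Load an alphabet from a small text config.

    One group per line: ``<group label><tab or spaces><comma-separated
    residues>``.  Blank lines and ``#`` comments are ignored.  The group
    label is informational; the residues define the group.
    """
    groups: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected '<label> <residues>'"
                )
            residues = parts[1].replace(",", "").replace(" ", "").upper()
            groups.append(residues)
    if not groups:
        raise ConfigurationError(f"{path}: no groups defined")
    return AlphabetMap(name=name or str(path), groups=tuple(groups))


def write_alphabet(alphabet: AlphabetMap, path) -> None:
    with open(path, "w") as fh:
        for k, group in enumerate(alphabet.groups, start=1):
            fh.write(f"g{k}\t{','.join(group)}\n")
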