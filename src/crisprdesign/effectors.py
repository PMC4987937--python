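"""PAM specifications and CRISPR effector presets.

A PAM pattern is an IUPAC-degenerate string anchored to one side of the
protospacer: 3' for Cas9-type effectors (NGG sits downstream of the spacer),
5' for Cpf1-type (TTTN sits upstream). Matching is asymmetric: degenerate
codes are legal in the pattern, while the genomic sequence must be concrete
A/C/G/T — an N in the genome never matches any pattern code, including N, so
assembly gaps never produce phantom targets.

Presets ship as an editable TSV resource (name, pam, anchor, guide_length,
cut_offset) covering the commonly used Cas9 orthologs and AsCpf1; every field
is overridable at run time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

FIVE_PRIME = "5"
THREE_PRIME = "3"

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

MAX_EXPAND_LEN = 12


class PamError(ValueError):
    """Invalid PAM pattern or matching misuse."""


@dataclass(frozen=True)
class PamSpec:
    """Degenerate PAM pattern with its anchor side relative to the protospacer."""

    pattern: str
    anchor: str  # FIVE_PRIME or THREE_PRIME
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise PamError("PAM pattern must be non-empty")
        if self.anchor not in (FIVE_PRIME, THREE_PRIME):
            raise PamError(f"anchor must be '5' or '3', got {self.anchor!r}")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class EffectorPreset:
    """Named effector: PAM spec, default spacer length and modeled cut geometry.

    ``cut_offset`` is measured in bp from the PAM-proximal protospacer end:
    3 for blunt-cutting Cas9-types (cut 3 bp inside the spacer, 5' of the PAM)
    and 18 for Cpf1-types (staggered cut far from the PAM). The value is a
    documented modeling constant used for cut-site reporting and primer
    centering, and can be overridden per run.
    """

    name: str
    pam: PamSpec
    default_guide_length: int
    cut_offset: int

    def __post_init__(self) -> None:
        if self.default_guide_length < 10:
            raise PamError(
                f"preset {self.name!r}: guide length must be >= 10, "
                f"got {self.default_guide_length}"
            )


def parse_pam(pattern: str, anchor: str, name: str = "custom") -> PamSpec:
    """Validate and normalise a user-supplied PAM pattern (U accepted as T)."""
    pattern = pattern.strip().upper().replace("U", "T")
    if not pattern:
        raise PamError("PAM pattern must be non-empty")
    for ch in pattern:
        if ch not in IUPAC:
            raise PamError(f"invalid IUPAC code {ch!r} in PAM pattern {pattern!r}")
    if anchor in ("5", "5'", "five_prime", "five"):
        anchor = FIVE_PRIME
    elif anchor in ("3", "3'", "three_prime", "three"):
        anchor = THREE_PRIME
    return PamSpec(pattern=pattern, anchor=anchor, name=name)


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff every base of ``seq`` lies in the corresponding pattern code.

    ``seq`` must be concrete genomic DNA; an N (or any non-ACGT character) in
    ``seq`` matches nothing, by design.
    """
    if len(pattern) != len(seq):
        raise PamError(
            f"pattern/sequence length mismatch: {len(pattern)} vs {len(seq)}"
        )
    for p, s in zip(pattern.upper(), seq.upper()):
        if p not in IUPAC:
            raise PamError(f"invalid IUPAC code {p!r} in pattern")
        if s not in "ACGT" or s not in IUPAC[p]:
            return False
    return True


def expand_iupac(pattern: str) -> set[str]:
    """All concrete ACGT strings matched by a degenerate pattern.

    Refuses patterns longer than 12 to guard against combinatorial blow-up
    (worst case 4^12 strings).
    """
    pattern = pattern.upper()
    if len(pattern) > MAX_EXPAND_LEN:
        raise PamError(
            f"refusing to expand pattern of length {len(pattern)} "
            f"(limit {MAX_EXPAND_LEN}): up to 4^{len(pattern)} strings"
        )
    choices = []
    for ch in pattern:
        if ch not in IUPAC:
            raise PamError(f"invalid IUPAC code {ch!r} in pattern")
        choices.append(sorted(IUPAC[ch]))
    return {"".join(combo) for combo in itertools.product(*choices)}


def _preset_rows(path: str | Path | None = None):
    if path is not None:
        text = Path(path).read_text()
    else:
        text = (
            resources.files("crisprdesign.resources")
            .joinpath("presets.tsv")
            .read_text()
        )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield line.split("\t")


def load_presets(path: str | Path | None = None) -> dict[str, EffectorPreset]:
    """Load the effector preset table (the bundled resource by default).

    Keys are lower-cased preset names, so lookup is case-insensitive.
    """
    presets: dict[str, EffectorPreset] = {}
    for fields in _preset_rows(path):
        if len(fields) != 5:
            raise PamError(f"preset row needs 5 fields, got {fields!r}")
        name, pam, anchor, guide_len, cut_offset = fields
        key = name.lower()
        if key in presets:
            raise PamError(f"duplicate preset name {name!r}")
        presets[key] = EffectorPreset(
            name=name,
            pam=parse_pam(pam, anchor, name=name),
            default_guide_length=int(guide_len),
            cut_offset=int(cut_offset),
        )
    return presets


def get_preset(name: str, path: str | Path | None = None) -> EffectorPreset:
    presets = load_presets(path)
    key = name.lower()
    if key not in presets:
        raise PamError(
            f"unknown effector {name!r}; available: {sorted(p.name for p in presets.values())}"
        )
    return presets[key]
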