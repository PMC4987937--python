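"""Per-guide quality metrics.

Four metrics are computed for every candidate:

* GC fraction of the protospacer (PAM excluded), with an "ideal" flag for the
  inclusive 40-80% window associated with efficient cutting.
* The legacy PAM-proximal G check — a G at position 20 of a 20-nt spacer,
  generalised to the final (PAM-adjacent) base for 3'-anchored effectors of
  any length. Not applicable to 5'-anchored (Cpf1-type) effectors, where the
  PAM-proximal base is position 1.
* Self-complementarity: the number of potential stems of >= 4 bp within the
  spacer (hairpins, requiring a loop of >= 3 nt between the stem halves) and
  between the spacer and the invariant sgRNA scaffold. Stems are counted as
  maximal duplexes — a 5 bp stem counts once, not as two 4 bp windows.
  Pairing is Watson-Crick by default; G.T wobble can be enabled.
* A pluggable position-feature efficiency model: a linear model over 1-2 nt
  features at fixed offsets within the scoring context window, with an
  identity or logistic link, loaded from a simple TSV format so published
  position-weight tables can be dropped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .scan import GuideCandidate

DEFAULT_MIN_STEM = 4
DEFAULT_MIN_LOOP = 3

_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = _WC_PAIRS | {("G", "T"), ("T", "G")}


class ModelError(ValueError):
    """Malformed or incompatible efficiency-model file."""


def load_backbone(path: str | Path | None = None) -> str:
    """The invariant sgRNA scaffold as DNA (bundled resource by default)."""
    if path is not None:
        text = Path(path).read_text()
    else:
        text = resources.files("crisprdesign.resources").joinpath("backbone.txt").read_text()
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return "".join(lines).upper().replace("U", "T")


def gc_fraction(protospacer: str) -> tuple[float, bool]:
    """GC fraction of the spacer and whether it falls in the ideal 40-80% window.

    Bounds are inclusive and checked in exact integer arithmetic, so a 20-mer
    with exactly 8 G/C (40.0%) is ideal.
    """
    if not protospacer:
        raise ValueError("empty protospacer")
    n = len(protospacer)
    gc = sum(1 for b in protospacer if b in "GC")
    ideal = (40 * n <= 100 * gc) and (100 * gc <= 80 * n)
    return gc / n, ideal


def pam_proximal_g(protospacer: str, anchor: str = "3") -> Optional[bool]:
    """Whether the PAM-proximal spacer base is G.

    For 3'-anchored effectors this is the final base (position 20 of a 20-nt
    guide; position L of an L-nt guide). For 5'-anchored effectors the check
    is not applicable and None is returned.
    """
    if anchor == "5":
        return None
    return protospacer[-1] == "G"


def _pairs(a: str, b: str, wobble: bool) -> bool:
    return (a, b) in (_WOBBLE_PAIRS if wobble else _WC_PAIRS)


def _antidiagonal_runs(ok: list[bool]) -> list[tuple[int, int]]:
    """Maximal runs of True: list of (start, length)."""
    runs = []
    i = 0
    n = len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def selfcomp(
    protospacer: str,
    backbone: str = "",
    min_stem: int = DEFAULT_MIN_STEM,
    min_loop: int = DEFAULT_MIN_LOOP,
    wobble: bool = False,
) -> int:
    """Count potential stems within the spacer and between spacer and scaffold.

    Intramolecular stems pair g[x] with g[y] antiparallel along an
    antidiagonal (x + y constant); a maximal run of >= ``min_stem``
    consecutive pairs whose innermost pair still leaves a loop of >=
    ``min_loop`` unpaired bases counts once. Intermolecular stems pair g[x]
    with backbone[y] along antidiagonals of the guide x backbone pair matrix,
    with no loop constraint. Each maximal duplex counts once.
    """
    if min_stem < 2:
        raise ValueError(f"min_stem must be >= 2, got {min_stem}")
    g = protospacer.upper()
    n = len(g)
    count = 0
    # intramolecular: antidiagonal d = x + y, pairs (x, d - x) with x < d - x
    for d in range(2 * n - 1):
        xs = [x for x in range(n) if 0 <= d - x < n and x < d - x]
        if not xs:
            continue
        ok = [_pairs(g[x], g[d - x], wobble) for x in xs]
        for start, length in _antidiagonal_runs(ok):
            if length < min_stem:
                continue
            # innermost pair is the run's last (largest x); loop = y - x - 1
            x_in = xs[start + length - 1]
            if (d - x_in) - x_in - 1 >= min_loop:
                count += 1
            else:
                # trim inner pairs violating the loop constraint, keep if still long enough
                usable = 0
                for k in range(length):
                    x = xs[start + k]
                    if (d - x) - x - 1 >= min_loop:
                        usable += 1
                if usable >= min_stem:
                    count += 1
    # guide vs backbone: antiparallel duplex pairs g[x] with b[y], x ascending, y descending
    b = backbone.upper().replace("U", "T")
    m = len(b)
    if m:
        for d in range(n + m - 1):  # antidiagonal x + y = d
            xs = [x for x in range(n) if 0 <= d - x < m]
            ok = [_pairs(g[x], b[d - x], wobble) for x in xs]
            for _, length in _antidiagonal_runs(ok):
                if length >= min_stem:
                    count += 1
    return count


@dataclass(frozen=True)
class EfficiencyModel:
    """Linear position-feature model over the scoring context window.

    ``window`` is (upstream, guide, pam, downstream) lengths in bp; feature
    offsets are 0-based positions within the concatenated context string, and
    k-mers are 1-2 nt. The score is intercept + sum of weights of matching
    features, passed through the link (identity, or logistic 1/(1+e^-s)).
    """

    name: str
    window: tuple[int, int, int, int]
    intercept: float
    features: tuple[tuple[int, str, float], ...]
    link: str = "identity"

    def __post_init__(self) -> None:
        if self.link not in ("identity", "logistic"):
            raise ModelError(f"unknown link {self.link!r}")
        total = sum(self.window)
        for i, (offset, kmer, _w) in enumerate(self.features):
            if not 1 <= len(kmer) <= 2:
                raise ModelError(f"feature {i}: k-mer length must be 1-2, got {kmer!r}")
            if not 0 <= offset <= total - len(kmer):
                raise ModelError(
                    f"feature {i}: offset {offset} with k-mer {kmer!r} exceeds "
                    f"window length {total}"
                )

    @property
    def guide_length(self) -> int:
        return self.window[1]


def load_model(path: str | Path) -> EfficiencyModel:
    """Load an efficiency model from TSV.

    Header lines ``# key=value`` define name, window (4 comma-separated
    lengths), link and intercept; each following row is
    ``offset<TAB>kmer<TAB>weight``. Errors name the offending row.
    """
    meta: dict[str, str] = {}
    features: list[tuple[int, str, float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ModelError(f"{path}:{lineno}: expected offset<TAB>kmer<TAB>weight")
        try:
            offset = int(parts[0])
        except ValueError:
            raise ModelError(f"{path}:{lineno}: non-integer offset {parts[0]!r}") from None
        kmer = parts[1].strip().upper()
        try:
            weight = float(parts[2])
        except ValueError:
            raise ModelError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}") from None
        features.append((offset, kmer, weight))
    for key in ("name", "window", "intercept"):
        if key not in meta:
            raise ModelError(f"{path}: missing '# {key}=...' header")
    window = tuple(int(x) for x in meta["window"].split(","))
    if len(window) != 4:
        raise ModelError(f"{path}: window must have 4 lengths, got {meta['window']!r}")
    try:
        return EfficiencyModel(
            name=meta["name"],
            window=window,  # type: ignore[arg-type]
            intercept=float(meta["intercept"]),
            features=tuple(features),
            link=meta.get("link", "identity"),
        )
    except ModelError as e:
        raise ModelError(f"{path}: {e}") from None


def write_model(model: EfficiencyModel, path: str | Path) -> None:
    """Write a model in the TSV format read by :func:`load_model` (exact round-trip)."""
    with open(path, "w") as fh:
        fh.write(f"# name={model.name}\n")
        fh.write(f"# window={','.join(str(w) for w in model.window)}\n")
        fh.write(f"# link={model.link}\n")
        fh.write(f"# intercept={model.intercept!r}\n")
        for offset, kmer, weight in model.features:
            fh.write(f"{offset}\t{kmer}\t{weight!r}\n")


def builtin_model() -> EfficiencyModel:
    """The bundled demonstration model (synthetic weights, documented format)."""
    with resources.as_file(
        resources.files("crisprdesign.resources").joinpath("models/example_linear.tsv")
    ) as p:
        return load_model(p)


def efficiency_score(
    candidate: GuideCandidate, model: EfficiencyModel
) -> Optional[float]:
    """Score a candidate with a position-feature model; None if unavailable.

    The candidate's context must match the model's window geometry exactly
    (total length, guide length, PAM length). The score is unavailable when
    the context is partial and any feature span touches N-padding.
    """
    ctx = candidate.context
    total = sum(model.window)
    if len(ctx) != total:
        raise ModelError(
            f"context length {len(ctx)} does not match model window {model.window}"
        )
    if model.guide_length != len(candidate.protospacer):
        raise ModelError(
            f"model guide length {model.guide_length} != run guide length "
            f"{len(candidate.protospacer)}"
        )
    if model.window[2] != len(candidate.pam_seq):
        raise ModelError(
            f"model PAM length {model.window[2]} != run PAM length {len(candidate.pam_seq)}"
        )
    pad_lo = candidate.pad_left
    pad_hi_start = total - candidate.pad_right
    s = model.intercept
    for offset, kmer, weight in model.features:
        span_end = offset + len(kmer)
        if candidate.partial_context and (offset < pad_lo or span_end > pad_hi_start):
            return None
        if ctx[offset:span_end] == kmer:
            s += weight
    if model.link == "logistic":
        return 1.0 / (1.0 + math.exp(-s))
    return s


@dataclass(frozen=True)
class ScoreSet:
    """All quality metrics for one candidate."""

    gc_fraction: float
    gc_ideal: bool
    pam_proximal_g: Optional[bool]
    selfcomp: int
    efficiency: Optional[float]
    model_name: str = ""


def score_candidate(
    candidate: GuideCandidate,
    model: Optional[EfficiencyModel] = None,
    backbone: str = "",
    anchor: str = "3",
    min_stem: int = DEFAULT_MIN_STEM,
    min_loop: int = DEFAULT_MIN_LOOP,
    wobble: bool = False,
) -> ScoreSet:
    """Compute the full metric set for one candidate."""
    gc, ideal = gc_fraction(candidate.protospacer)
    eff = efficiency_score(candidate, model) if model is not None else None
    return ScoreSet(
        gc_fraction=gc,
        gc_ideal=ideal,
        pam_proximal_g=pam_proximal_g(candidate.protospacer, anchor),
        selfcomp=selfcomp(
            candidate.protospacer, backbone, min_stem=min_stem,
            min_loop=min_loop, wobble=wobble,
        ),
        efficiency=eff,
        model_name=model.name if model is not None else "",
    )
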