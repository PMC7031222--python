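"""Derive up/down gene signatures from DE tables and translate them across species.

A signature is a pair of disjoint gene sets (up-regulated, down-regulated)
summarizing one time-point contrast of the regeneration time course.  The
selection is fully reproducible via four thresholds: minimum absolute log2
fold change, maximum adjusted p, and a size window — defaults chosen so that
signatures land in the few-dozen-to-hundreds range typical of connectivity
mapping queries.

Cross-species translation (e.g. zebrafish -> human, as needed to query a
human perturbation database) applies an ortholog map under an explicit
one-to-many policy; genes whose orthologs land in both directions are
removed from both, since direction is the signal and ambiguity is noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import SignatureError, ValidationError
from .io_formats import DETable, OrthologMap

__all__ = [
    "Signature",
    "SignaturePanel",
    "TranslationReport",
    "extract_signature",
    "translate_signature",
    "restrict_to_universe",
    "DEFAULT_LFC_MIN",
    "DEFAULT_Q_MAX",
    "DEFAULT_MIN_SIZE",
    "DEFAULT_MAX_SIZE",
]

DEFAULT_LFC_MIN = 1.0
DEFAULT_Q_MAX = 0.05
DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 500

POLICIES = ("expand", "drop_ambiguous", "first")


@dataclass(frozen=True)
class Signature:
    """Named up/down gene sets for one contrast; the sets are disjoint."""

    name: str
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    contrast_label: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("signature name must be non-empty")
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        if self.up_genes & self.down_genes:
            raise ValidationError(
                f"signature {self.name!r}: up and down sets overlap: "
                f"{sorted(self.up_genes & self.down_genes)[:5]}"
            )
        if not (self.up_genes or self.down_genes):
            raise ValidationError(f"signature {self.name!r} is empty")

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes


@dataclass(frozen=True)
class SignaturePanel:
    """An ordered panel of S signatures with unique names."""

    signatures: tuple[Signature, ...]

    def __post_init__(self) -> None:
        sigs = tuple(self.signatures)
        object.__setattr__(self, "signatures", sigs)
        if not sigs:
            raise ValidationError("a signature panel needs at least one signature")
        names = [s.name for s in sigs]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate signature names in panel: {names}")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]


@dataclass(frozen=True)
class TranslationReport:
    """What happened to each source gene during ortholog translation."""

    conflict_genes: frozenset[str]  # targets mapped into both directions, removed
    unmapped_genes: frozenset[str]  # source genes with no usable target


def extract_signature(
    de: DETable,
    lfc_min: float = DEFAULT_LFC_MIN,
    q_max: float = DEFAULT_Q_MAX,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    name: str | None = None,
) -> Signature:
    """Threshold a DE table into an up/down signature.

    Up = genes with ``log2fc >= lfc_min`` and ``p_adj <= q_max``; down is the
    mirrored criterion.  If the combined size exceeds ``max_size``, the
    ``max_size`` genes with largest ``|log2fc|`` are kept (ties broken by
    gene id, ascending).  A combined size below ``min_size`` is an error.
    """
    if lfc_min <= 0:
        raise ValueError(f"lfc_min must be > 0, got {lfc_min}")
    if not 0 < q_max <= 1:
        raise ValueError(f"q_max must be in (0, 1], got {q_max}")
    if len(de) == 0:
        raise ValueError("DE table is empty")
    t = de.table
    sig_rows = t[(t["p_adj"] <= q_max) & (t["log2fc"].abs() >= lfc_min)]
    total = len(sig_rows)
    if total < min_size:
        raise SignatureError(
            f"signature too small for contrast {de.contrast_label!r}: "
            f"{total} genes < min_size={min_size}"
        )
    if total > max_size:
        order = sig_rows.assign(abs_lfc=sig_rows["log2fc"].abs()).sort_values(
            ["abs_lfc", "gene_id"], ascending=[False, True], kind="mergesort"
        )
        sig_rows = order.head(max_size)
    up = frozenset(sig_rows.loc[sig_rows["log2fc"] > 0, "gene_id"])
    down = frozenset(sig_rows.loc[sig_rows["log2fc"] < 0, "gene_id"])
    return Signature(
        name=name or de.contrast_label,
        up_genes=up,
        down_genes=down,
        contrast_label=de.contrast_label,
    )


def _map_gene(gene: str, mapping: dict[str, list[str]], policy: str) -> list[str]:
    targets = sorted(set(mapping.get(gene, ())))
    if not targets:
        return []
    if policy == "expand":
        return targets
    if policy == "drop_ambiguous":
        return targets if len(targets) == 1 else []
    return [targets[0]]  # "first": lexicographically smallest


def translate_signature(
    sig: Signature,
    ortholog_map: OrthologMap,
    policy: str = "expand",
) -> tuple[Signature, TranslationReport]:
    """Translate a signature across species through an ortholog map.

    One-to-many mappings are handled per ``policy`` (expand all targets, drop
    ambiguous sources, or keep the lexicographically first target).  Unmapped
    source genes are dropped.  A target gene reached from both the up and the
    down set is a direction conflict and is removed from both sets.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}, got {policy!r}")
    mapping = ortholog_map.as_dict()
    up, down, unmapped = set(), set(), set()
    for gene in sig.up_genes:
        targets = _map_gene(gene, mapping, policy)
        (up.update(targets) if targets else unmapped.add(gene))
    for gene in sig.down_genes:
        targets = _map_gene(gene, mapping, policy)
        (down.update(targets) if targets else unmapped.add(gene))
    conflicts = up & down
    up -= conflicts
    down -= conflicts
    if not (up or down):
        raise SignatureError(
            f"untranslatable signature {sig.name!r}: no genes survive translation"
        )
    translated = Signature(
        name=sig.name,
        up_genes=frozenset(up),
        down_genes=frozenset(down),
        contrast_label=sig.contrast_label,
    )
    report = TranslationReport(
        conflict_genes=frozenset(conflicts), unmapped_genes=frozenset(unmapped)
    )
    return translated, report


def restrict_to_universe(
    sig: Signature, universe: frozenset[str] | set[str]
) -> tuple[Signature, int, int]:
    """Intersect both signature sets with a gene universe.

    Returns the restricted signature and the retained counts (k_up, k_down).
    Signature genes absent from the profile matrix cannot be ranked, so they
    are dropped before scoring.
    """
    universe = frozenset(universe)
    up = sig.up_genes & universe
    down = sig.down_genes & universe
    if not (up or down):
        raise SignatureError(f"signature {sig.name!r} disjoint from universe")
    restricted = replace(sig, up_genes=frozenset(up), down_genes=frozenset(down))
    return restricted, len(up), len(down)
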