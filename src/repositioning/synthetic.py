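"""Synthetic fixtures: time-course DE tables, ortholog maps and CMap-like
profile matrices with planted connectivity.

The generator emulates the study conditions of a desk-scale connectivity
mapping screen: a multi-timepoint injury-response transcriptome (per-contrast
DE tables), a cross-species ortholog map, and a drug-perturbation database
of ranked profiles in which selected "planted" compounds are constructed to
match (or oppose) the signature panel at a controlled effect size.

Planting happens directly in rank space (redraw-then-backfill, each column
remains a permutation of ``1..n``): for a planted positive instance a
fraction ``phi`` of each signature's up genes gets its rank redrawn as
``max(1, ceil(u * (1 - delta) * n))`` (pushed toward the top) and the down
genes are pushed symmetrically toward the bottom; negative planting mirrors
this.  ``delta = 0`` reduces to the uniform null, ``delta = 1`` pins the
affected genes to the extreme ranks.

A single global seed fans out to per-component streams by stable hashing of
``(seed, component name)``, so adding a component never shifts another's
draws.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import DETable, OrthologMap, ProfileMatrix
from .signatures import Signature, SignaturePanel

__all__ = [
    "PlantedCompound",
    "SimConfig",
    "child_seed",
    "simulate_timecourse_de",
    "simulate_ortholog_map",
    "simulate_profile_matrix",
    "random_panel",
    "simulate_study",
]

_CELL_LINES = ("MCF7", "PC3", "HL60", "SKMEL5")


def child_seed(seed: int, component: str) -> int:
    """Stable per-component seed derived from the global seed (< 2^31)."""
    digest = hashlib.blake2b(
        f"{seed}:{component}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass(frozen=True)
class PlantedCompound:
    """A compound constructed to match (or oppose) the signature panel."""

    compound_id: str
    direction: str  # "positive" | "negative"
    effect_size: float  # delta in [0, 1]
    fraction_affected: float  # phi in (0, 1]

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValidationError(f"bad planted direction {self.direction!r}")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValidationError(f"effect size {self.effect_size} outside [0, 1]")
        if not 0.0 < self.fraction_affected <= 1.0:
            raise ValidationError(
                f"fraction affected {self.fraction_affected} outside (0, 1]"
            )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen."""

    n_genes: int = 2000
    n_compounds: int = 100
    instances_per_compound: int = 2
    panel_size: int = 3
    planted: tuple[PlantedCompound, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.n_genes < 2 or self.n_compounds < 1:
            raise ValidationError("need n_genes >= 2 and n_compounds >= 1")
        if self.instances_per_compound < 1 or self.panel_size < 1:
            raise ValidationError("instances_per_compound and panel_size must be >= 1")
        ids = set(self.compound_ids)
        for p in self.planted:
            if p.compound_id not in ids:
                raise ValidationError(
                    f"planted compound {p.compound_id!r} does not exist"
                )

    @property
    def compound_ids(self) -> list[str]:
        return [f"drug{i:04d}" for i in range(self.n_compounds)]


def simulate_timecourse_de(
    n_genes: int,
    n_timepoints: int,
    n_signature_genes: int,
    lfc_effect: float = 2.0,
    seed: int = 0,
    gene_prefix: str = "zf:g",
) -> list[DETable]:
    """Per-timepoint DE tables with a planted differential gene subset.

    Each timepoint plants ``n_signature_genes`` genes with ``|log2fc| >=
    lfc_effect`` and ``p_adj < 0.05``; background genes get small-noise fold
    changes and uniform adjusted p-values.  Deterministic given ``seed``.
    """
    if n_signature_genes > n_genes:
        raise ValidationError(
            f"n_signature_genes={n_signature_genes} exceeds n_genes={n_genes}"
        )
    if n_timepoints < 1 or n_genes < 1:
        raise ValidationError("need n_timepoints >= 1 and n_genes >= 1")
    genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    tables = []
    for t in range(n_timepoints):
        rng = np.random.default_rng(child_seed(seed, f"timecourse:{t}"))
        lfc = rng.normal(0.0, 0.2, size=n_genes)
        padj = rng.uniform(0.0, 1.0, size=n_genes)
        idx = rng.choice(n_genes, size=n_signature_genes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_signature_genes)
        lfc[idx] = signs * (lfc_effect + rng.exponential(0.5, size=n_signature_genes))
        padj[idx] = rng.uniform(0.0, 0.05, size=n_signature_genes) * 0.999
        label = f"t{t + 1}_vs_baseline"
        tables.append(DETable(
            contrast_label=label,
            table=pd.DataFrame(
                {"gene_id": genes, "log2fc": lfc, "p_adj": padj}
            ),
        ))
    return tables


def simulate_ortholog_map(
    source_genes: list[str],
    target_prefix: str = "hs:g",
    frac_one_to_many: float = 0.0,
    frac_unmapped: float = 0.0,
    seed: int = 0,
) -> OrthologMap:
    """A source -> target map with requested one-to-many / unmapped fractions.

    With both fractions zero the map is a bijection.  Deterministic given
    ``seed``; counts match the requested fractions within rounding.
    """
    if not 0.0 <= frac_one_to_many <= 1.0 or not 0.0 <= frac_unmapped <= 1.0:
        raise ValidationError("fractions must be in [0, 1]")
    if frac_one_to_many + frac_unmapped > 1.0:
        raise ValidationError("fraction sum exceeds 1")
    rng = np.random.default_rng(child_seed(seed, "ortholog_map"))
    src = sorted(source_genes)
    n = len(src)
    n_unmapped = round(frac_unmapped * n)
    n_multi = round(frac_one_to_many * n)
    shuffled = list(src)
    rng.shuffle(shuffled)
    unmapped = set(shuffled[:n_unmapped])
    multi = set(shuffled[n_unmapped:n_unmapped + n_multi])
    rows = []
    for i, s in enumerate(src):
        if s in unmapped:
            continue
        rows.append((s, f"{target_prefix}{i:05d}"))
        if s in multi:
            rows.append((s, f"{target_prefix}{i:05d}x"))
    return OrthologMap(pairs=pd.DataFrame(
        rows, columns=["source_gene", "target_gene"]
    ))


def random_panel(
    universe: list[str],
    panel_size: int,
    genes_per_side: int = 20,
    seed: int = 0,
) -> SignaturePanel:
    """A panel of signatures with disjoint up/down sets drawn from a universe."""
    need = panel_size * 2 * genes_per_side
    if need > len(universe):
        raise ValidationError(
            f"universe of {len(universe)} cannot host {panel_size} signatures "
            f"of {2 * genes_per_side} genes"
        )
    rng = np.random.default_rng(child_seed(seed, "panel"))
    chosen = rng.choice(len(universe), size=need, replace=False)
    sigs = []
    pos = 0
    for s in range(panel_size):
        up = frozenset(universe[i] for i in chosen[pos:pos + genes_per_side])
        pos += genes_per_side
        down = frozenset(universe[i] for i in chosen[pos:pos + genes_per_side])
        pos += genes_per_side
        sigs.append(Signature(name=f"sig{s + 1}", up_genes=up, down_genes=down))
    return SignaturePanel(tuple(sigs))


def _assign_extreme(
    desired: list[tuple[str, int, bool]], taken: np.ndarray
) -> dict[str, int]:
    """Place planted genes at (or next to) their desired ranks.

    ``desired`` holds (gene, target_rank, want_low); collisions bump a
    low-seeking gene to the next free rank above its target and a
    high-seeking gene to the next free rank below.
    """
    n = taken.size
    placed: dict[str, int] = {}
    for gene, d, want_low in desired:
        d = min(max(d, 1), n)
        if want_low:
            scan = range(d, n + 1)
            fallback = range(d - 1, 0, -1)
        else:
            scan = range(d, 0, -1)
            fallback = range(d + 1, n + 1)
        slot = next((r for r in scan if not taken[r - 1]), None)
        if slot is None:
            slot = next(r for r in fallback if not taken[r - 1])
        taken[slot - 1] = True
        placed[gene] = slot
    return placed


def simulate_profile_matrix(
    cfg: SimConfig,
    panel: SignaturePanel,
    universe: list[str] | None = None,
) -> ProfileMatrix:
    """A ranked profile matrix with uniform-null columns and planted compounds.

    Every non-planted instance is an independent uniform random permutation
    of ``1..n``.  Planted instances redraw the ranks of an affected fraction
    of the panel's signature genes toward the matching extreme and backfill
    the remaining genes in random order, so every column stays a permutation.
    """
    panel_genes = sorted(set().union(*(s.genes() for s in panel)))
    if universe is None:
        n_bg = cfg.n_genes - len(panel_genes)
        if n_bg < 0:
            raise ValidationError(
                f"panel has {len(panel_genes)} genes but universe size is "
                f"{cfg.n_genes}"
            )
        universe = panel_genes + [f"bg:g{i:05d}" for i in range(n_bg)]
        universe = sorted(universe)
    else:
        missing = set(panel_genes) - set(universe)
        if missing:
            raise ValidationError(
                f"panel genes missing from universe: {sorted(missing)[:5]}"
            )
    n = len(universe)
    gene_index = {g: i for i, g in enumerate(universe)}
    up_set = set().union(*(s.up_genes for s in panel))
    down_set = set().union(*(s.down_genes for s in panel))
    # genes with conflicting directions across signatures carry no coherent
    # signal to plant; leave their ranks at the uniform null
    conflicted = up_set & down_set
    up_all = sorted(up_set - conflicted)
    down_all = sorted(down_set - conflicted)
    planted_by_id = {p.compound_id: p for p in cfg.planted}

    instances, ann_rows = [], []
    columns = []
    for ci, compound in enumerate(cfg.compound_ids):
        for j in range(cfg.instances_per_compound):
            inst = f"{compound}.{j + 1}"
            instances.append(inst)
            ann_rows.append((inst, compound, _CELL_LINES[j % len(_CELL_LINES)]))
            rng = np.random.default_rng(child_seed(cfg.seed, f"instance:{inst}"))
            plant = planted_by_id.get(compound)
            col = np.empty(n, dtype=np.int64)
            if plant is None or plant.effect_size == 0.0:
                col[:] = rng.permutation(n) + 1
            else:
                col[:] = _planted_column(
                    plant, up_all, down_all, gene_index, n, rng
                )
            columns.append(col)
    values = np.stack(columns, axis=1)
    annotations = pd.DataFrame(
        ann_rows, columns=["instance_id", "compound_id", "cell_line"]
    )
    return ProfileMatrix(
        gene_universe=list(universe),
        instances=instances,
        values=values,
        annotations=annotations,
        is_ranks=True,
    )


def _planted_column(
    plant: PlantedCompound,
    up_all: list[str],
    down_all: list[str],
    gene_index: dict[str, int],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    delta, phi = plant.effect_size, plant.fraction_affected
    k = len(up_all) + len(down_all)
    if phi * k < 1.0:
        warnings.warn(
            f"planted compound {plant.compound_id!r}: phi*k = {phi * k:.2f} < 1, "
            "no genes moved", stacklevel=3
        )
        return rng.permutation(n) + 1
    n_up = int(round(phi * len(up_all)))
    n_down = int(round(phi * len(down_all)))
    aff_up = [up_all[i] for i in rng.choice(len(up_all), n_up, replace=False)] \
        if n_up else []
    aff_down = [down_all[i] for i in rng.choice(len(down_all), n_down, replace=False)] \
        if n_down else []
    # positive plant: up genes toward rank 1, down genes toward rank n
    low_set, high_set = (aff_up, aff_down) if plant.direction == "positive" \
        else (aff_down, aff_up)
    desired = []
    for gene in low_set:
        u = rng.uniform()
        desired.append((gene, max(1, int(np.ceil(u * (1.0 - delta) * n))), True))
    for gene in high_set:
        u = rng.uniform()
        desired.append((gene, n + 1 - max(1, int(np.ceil(u * (1.0 - delta) * n))),
                        False))
    taken = np.zeros(n, dtype=bool)
    placed = _assign_extreme(desired, taken)
    col = np.empty(n, dtype=np.int64)
    remaining_ranks = np.flatnonzero(~taken) + 1
    rng.shuffle(remaining_ranks)
    it = iter(remaining_ranks)
    placed_idx = {gene_index[g]: r for g, r in placed.items()}
    for i in range(n):
        col[i] = placed_idx[i] if i in placed_idx else next(it)
    return col


def simulate_study(
    cfg: SimConfig,
    outdir,
    lfc_effect: float = 2.0,
    genes_per_side: int = 20,
    frac_one_to_many: float = 0.0,
    frac_unmapped: float = 0.0,
):
    """Write a complete, internally consistent fixture directory.

    Generates the whole chain on disk: per-timepoint DE tables in the source
    species, an ortholog map, the translated signature panel (GMT), a ranked
    profile matrix (GCT 1.2) with its annotation table, and a truth table of
    planted compounds.  Returns the paths written.
    """
    from pathlib import Path

    from .io_formats import write_profile_matrix
    from .integration import panel_to_gmt
    from .signatures import extract_signature, translate_signature

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de_tables = simulate_timecourse_de(
        n_genes=cfg.n_genes,
        n_timepoints=cfg.panel_size,
        n_signature_genes=2 * genes_per_side,
        lfc_effect=lfc_effect,
        seed=cfg.seed,
    )
    source_genes = de_tables[0].table["gene_id"].tolist()
    omap = simulate_ortholog_map(
        source_genes,
        frac_one_to_many=frac_one_to_many,
        frac_unmapped=frac_unmapped,
        seed=cfg.seed,
    )
    sigs = []
    for t in de_tables:
        sig = extract_signature(t, lfc_min=min(1.0, lfc_effect), q_max=0.05)
        tsig, _ = translate_signature(sig, omap, policy="expand")
        sigs.append(tsig)
    panel = SignaturePanel(tuple(sigs))
    universe = sorted(set(omap.pairs["target_gene"]))
    pm = simulate_profile_matrix(cfg, panel, universe=universe)

    paths = {}
    for t in de_tables:
        p = outdir / f"de_{t.contrast_label}.tsv"
        t.table.to_csv(p, sep="\t", index=False)
        paths[f"de:{t.contrast_label}"] = p
    omap.pairs.to_csv(outdir / "ortholog_map.tsv", sep="\t", index=False)
    paths["ortholog_map"] = outdir / "ortholog_map.tsv"
    panel_to_gmt(panel, outdir / "signatures.gmt")
    paths["signatures"] = outdir / "signatures.gmt"
    write_profile_matrix(pm, outdir / "profiles.gct")
    paths["profiles"] = outdir / "profiles.gct"
    pm.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    paths["annotations"] = outdir / "annotations.tsv"
    truth = pd.DataFrame(
        [(p.compound_id, p.direction, p.effect_size, p.fraction_affected)
         for p in cfg.planted],
        columns=["compound_id", "direction", "effect_size", "fraction_affected"],
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    return paths


def run_synthetic_screen(
    cfg: SimConfig,
    genes_per_side: int = 20,
    method: str = "auto",
):
    """Generate one synthetic screen in memory and run scoring + integration.

    Returns a dict with the signature panel, the per-compound aggregated
    scores and the integrated positive/negative result lists.  Used for
    calibration and power studies where file round-trips would only add
    noise-free overhead.
    """
    from .connectivity import score_panel
    from .integration import integrate_signatures

    universe = [f"hs:g{i:05d}" for i in range(cfg.n_genes)]
    panel = random_panel(universe, cfg.panel_size,
                         genes_per_side=genes_per_side, seed=cfg.seed)
    pm = simulate_profile_matrix(cfg, panel, universe=universe)
    _per_instance, aggregated = score_panel(panel, pm, method=method)
    out = {"panel": panel, "aggregated": aggregated}
    for direction in ("positive", "negative"):
        out[direction] = integrate_signatures(aggregated, direction, method=method)
    return out
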