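"""Seeded synthetic KGML pathway generator with ground-truth manifests.

The generator emulates the KEGG hand-drawn map style: metabolite circles on a
loose grid (columns of chained reactions, rows of aligned compounds), gene
rectangles midway along each reaction edge, occasional branches, a few
compound pairs with parallel reactions, and rounded "another map" boxes at
chain ends linked by ``maplink`` relations.  Grid positions carry small
sub-tolerance jitter so alignment must be *inferred*, as on real maps.

Every emitted pathway comes with a :class:`Manifest` recording exact counts
and the structural ground truth (expected alignment clusters per axis,
expected reaction groups), so each downstream stage can be tested without any
download.  Names are synthetic identifiers, not real biochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .kgml_io import AmbiguityFlag, AmbiguityReason

COMPOUND_SIZE = (8.0, 8.0)  # KEGG compound circle
GENE_SIZE = (46.0, 17.0)  # KEGG gene-product rectangle
MAP_SIZE = (46.0, 17.0)

# must mirror translator.place_initial defaults: manifest cluster bookkeeping
# predicts where reaction-group processes end up
_GROUP_SPACING = 25.0


@dataclass(frozen=True)
class SynthSpec:
    n_chains: int = 3
    chain_length: int = 4
    branch_prob: float = 0.15
    reversible_fraction: float = 0.3
    multi_reaction_pairs: int = 1
    n_maplinks: int = 1
    grid: float = 90.0
    jitter: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        for p in (self.branch_prob, self.reversible_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        n_pairs = self.n_chains * max(self.chain_length - 1, 0)
        if self.multi_reaction_pairs > n_pairs:
            raise ValueError(
                f"multi_reaction_pairs={self.multi_reaction_pairs} exceeds the "
                f"{n_pairs} available compound pairs"
            )
        if self.n_maplinks > 0 and self.chain_length < 1:
            raise ValueError("maplinks need at least one compound per chain")


@dataclass
class Manifest:
    n_compounds: int = 0
    n_genes: int = 0
    n_maps: int = 0
    n_reactions: int = 0
    n_relations: int = 0
    n_reversible: int = 0
    expected_glyphs: int = 0
    expected_arcs: int = 0
    expected_x_groups: int = 0
    expected_y_groups: int = 0
    expected_reaction_groups: int = 0
    multi_pair_sizes: list[int] = field(default_factory=list)
    injected_flags: list[AmbiguityFlag] = field(default_factory=list)


def _cluster_count(coords: list[float], tol: float = 1e-6) -> int:
    """Number of 1-D single-linkage clusters of size >= 2 (exact positions)."""
    if not coords:
        return 0
    xs = sorted(coords)
    groups = []
    current = [xs[0]]
    for v in xs[1:]:
        if v - current[-1] <= tol:
            current.append(v)
        else:
            groups.append(current)
            current = [v]
    groups.append(current)
    return sum(1 for g in groups if len(g) >= 2)


def generate_kgml(spec: SynthSpec) -> tuple[str, Manifest]:
    """Generate one synthetic pathway; deterministic per ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    man = Manifest()

    x0, y0 = 120.0, 80.0
    col_spacing = 1.8 * spec.grid

    entries: list[dict] = []
    reactions: list[dict] = []
    relations: list[dict] = []
    # ideal (jitter-free) coordinates of compounds and of where processes will
    # be placed, used for the alignment-cluster ground truth
    ideal_x: list[float] = []
    ideal_y: list[float] = []

    next_entry = 1
    next_reaction = 1

    def jit() -> float:
        if spec.jitter == 0:
            return 0.0
        return float(rng.uniform(-spec.jitter, spec.jitter))

    def add_entry(etype, name, x, y, size, ideal=None, reaction=None):
        nonlocal next_entry
        eid = str(next_entry)
        next_entry += 1
        entries.append(
            dict(id=eid, type=etype, name=name, x=x + jit(), y=y + jit(), w=size[0],
                 h=size[1], reaction=reaction)
        )
        if ideal is not None:
            ideal_x.append(ideal[0])
            ideal_y.append(ideal[1])
        return eid

    def add_reaction(sub, prod, gene_xy, gene_ideal, reversible):
        nonlocal next_reaction
        rname = f"rn:R{next_reaction:05d}"
        rid = f"r{next_reaction}"
        next_reaction += 1
        gid = add_entry(
            "gene", f"gene:G{next_reaction - 1:05d}", gene_xy[0], gene_xy[1], GENE_SIZE,
            ideal=gene_ideal, reaction=rname,
        )
        reactions.append(
            dict(id=rid, name=rname, type="reversible" if reversible else "irreversible",
                 substrate=sub, product=prod)
        )
        man.n_genes += 1
        man.n_reactions += 1
        if reversible:
            man.n_reversible += 1
        return rid, gid

    # choose which consecutive pairs carry parallel reactions (deterministic scan)
    all_pairs = [
        (c, i) for c in range(spec.n_chains) for i in range(spec.chain_length - 1)
    ]
    multi_pairs = set(all_pairs[: spec.multi_reaction_pairs])

    chain_compounds: list[list[str]] = []
    for c in range(spec.n_chains):
        cx = x0 + c * col_spacing
        ids: list[str] = []
        for i in range(spec.chain_length):
            cy = y0 + i * spec.grid
            ids.append(
                add_entry("compound", f"cpd:C{next_entry:05d}", cx, cy, COMPOUND_SIZE,
                          ideal=(cx, cy))
            )
            man.n_compounds += 1
        chain_compounds.append(ids)

        for i in range(spec.chain_length - 1):
            y_mid = y0 + (i + 0.5) * spec.grid
            reversible = bool(rng.random() < spec.reversible_fraction)
            if (c, i) in multi_pairs:
                k = int(rng.integers(2, 4))  # 2 or 3 parallel reactions
                man.multi_pair_sizes.append(k)
                man.expected_reaction_groups += 1
                for j in range(k):
                    # raw gene positions fan out; layout re-centers group
                    # processes on the pair axis at fixed spacing
                    gx = cx + 30.0 * (j + 1)
                    py = y_mid + (j - (k - 1) / 2.0) * _GROUP_SPACING
                    add_reaction(ids[i], ids[i + 1], (gx, y_mid), (cx, py), reversible)
            else:
                add_reaction(ids[i], ids[i + 1], (cx, y_mid), (cx, y_mid), reversible)

            # side branch off the upper compound of this pair
            if i < spec.chain_length - 1 and rng.random() < spec.branch_prob:
                bx = cx + 0.9 * spec.grid
                bid = add_entry(
                    "compound", f"cpd:C{next_entry:05d}", bx, y0 + i * spec.grid,
                    COMPOUND_SIZE, ideal=(bx, y0 + i * spec.grid),
                )
                man.n_compounds += 1
                add_reaction(
                    ids[i], bid, (cx + 0.45 * spec.grid, y0 + i * spec.grid),
                    (cx + 0.45 * spec.grid, y0 + i * spec.grid),
                    bool(rng.random() < spec.reversible_fraction),
                )

    for m in range(spec.n_maplinks):
        c = m % spec.n_chains
        extra = m // spec.n_chains
        cx = x0 + c * col_spacing
        my = y0 + (spec.chain_length + extra) * spec.grid
        mid = add_entry("map", f"path:map{m + 1:05d}", cx, my, MAP_SIZE)
        man.n_maps += 1
        partner = chain_compounds[c][-1]
        relations.append(
            dict(entry1=partner, entry2=mid, type="maplink", via=partner)
        )
        man.n_relations += 1

    man.expected_x_groups = _cluster_count(ideal_x)
    man.expected_y_groups = _cluster_count(ideal_y)
    # Table-1 count law: every reaction has exactly one catalyst here
    n_terminals = man.n_relations
    man.expected_glyphs = man.n_compounds + man.n_maps + n_terminals + 2 * man.n_reactions
    man.expected_arcs = man.n_relations + 3 * man.n_reactions

    root = etree.Element(
        "pathway", name=f"path:syn{spec.seed:05d}", org="syn",
        number=f"{spec.seed:05d}", title="Synthetic pathway",
    )
    for e in entries:
        attrs = dict(id=e["id"], name=e["name"], type=e["type"])
        if e["reaction"]:
            attrs["reaction"] = e["reaction"]
        el = etree.SubElement(root, "entry", **attrs)
        etree.SubElement(
            el, "graphics", name=e["name"].split(":", 1)[-1],
            x=f"{e['x']:.2f}", y=f"{e['y']:.2f}",
            width=f"{e['w']:g}", height=f"{e['h']:g}",
            type="circle" if e["type"] == "compound" else "rectangle",
        )
    for rel in relations:
        el = etree.SubElement(
            root, "relation", entry1=rel["entry1"], entry2=rel["entry2"], type=rel["type"]
        )
        etree.SubElement(el, "subtype", name="compound", value=rel["via"])
    for r in reactions:
        el = etree.SubElement(root, "reaction", id=r["id"], name=r["name"], type=r["type"])
        etree.SubElement(el, "substrate", id=r["substrate"], name=f"cpd:{r['substrate']}")
        etree.SubElement(el, "product", id=r["product"], name=f"cpd:{r['product']}")

    text = etree.tostring(root, pretty_print=True, encoding="unicode")
    return text, man


CORRUPTION_MODES = ("drop_reaction_type", "drop_products", "orphan_role")


def corrupt_kgml(
    kgml_text: str, modes: list[str] | tuple[str, ...], seed: int
) -> tuple[str, list[AmbiguityFlag]]:
    """Inject KGML information defects and return the ground-truth flag list.

    Each requested mode is applied to one randomly chosen (seeded) eligible
    reaction; a mode with no eligible target is skipped with a notice.
    """
    rng = np.random.default_rng(seed)
    root = etree.fromstring(kgml_text.encode("utf-8"))
    flags: list[AmbiguityFlag] = []

    def rid_of(el) -> str:
        return el.get("id") or el.get("name", "")

    for mode in modes:
        if mode not in CORRUPTION_MODES:
            raise ValueError(f"unknown corruption mode {mode!r}")
        reactions = root.findall("reaction")
        if mode == "drop_reaction_type":
            eligible = [r for r in reactions if r.get("type") is not None]
            reason = AmbiguityReason.MISSING_REVERSIBILITY
        elif mode == "drop_products":
            eligible = [r for r in reactions if r.findall("product")]
            reason = AmbiguityReason.MISSING_PARTICIPANTS
        else:  # orphan_role
            eligible = [r for r in reactions if r.findall("substrate")]
            reason = AmbiguityReason.MISSING_ROLE
        # avoid reusing an already corrupted reaction while possible, so each
        # injected flag has a distinct target
        hit = {f.target for f in flags}
        fresh = [r for r in eligible if rid_of(r) not in hit]
        pool = fresh or eligible
        if not pool:
            import logging

            logging.getLogger(__name__).info("no eligible element for mode %s", mode)
            continue
        target = pool[int(rng.integers(len(pool)))]
        if mode == "drop_reaction_type":
            del target.attrib["type"]
        elif mode == "drop_products":
            for p in target.findall("product"):
                target.remove(p)
        else:
            sub = target.findall("substrate")[0]
            sub.tag = "participant"
            if not target.findall("substrate"):
                # orphaning the only substrate also empties the substrate list,
                # which is a second, distinct defect
                flags.append(
                    AmbiguityFlag(rid_of(target), AmbiguityReason.MISSING_PARTICIPANTS)
                )
        flags.append(AmbiguityFlag(rid_of(target), reason))

    return etree.tostring(root, pretty_print=True, encoding="unicode"), flags
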