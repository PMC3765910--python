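# kgml2sbgn

Automatic translation of KEGG metabolic pathway maps (KGML files) into SBGN
Process Description (PD) maps, with a layout that stays recognizably the
original hand-drawn KEGG pathway.

KEGG pathway maps are drawn by human curators, and their KGML files carry the
node positions of that drawing — but no edge routes, and no room for the
nodes an SBGN translation must add. Translating a KEGG reaction to SBGN PD
turns each gene-product rectangle into a **macromolecule** (the enzyme) plus
a **process** node joined by a catalysis arc; compounds become **simple
chemicals**, links to other maps become **submaps** with border **terminals**
and equivalence arcs. The extra nodes break the curated layout. This package
repairs it with constraint-based layout instead of re-laying-out from
scratch:

1. **Translate** KGML to SBGN PD one-to-one (irreversible reactions:
   consumption + production arcs; reversible reactions: production arcs on
   both sides; several parallel reactions between one compound pair form a
   *reaction group*). Defective KGML (missing reversibility, missing
   substrate/product roles or participants) is detected and the affected
   elements are flagged for red rendering.
2. **Infer layout intent** from the original coordinates: per axis,
   compounds and processes within a small tolerance of each other join an
   *alignment group* with a shared guide variable; separation constraints
   between consecutive guides preserve the original left-to-right and
   top-to-bottom order. Style constraints pin each enzyme at a fixed offset
   from its process, terminals to submap borders, children inside parents,
   and reaction-group processes into evenly spaced stacks.
3. **Solve node positions** by projecting desired positions onto the
   separation-constraint system `u + g ≤ v` / `u + g = v` — the exact
   minimizer of `Σᵢ (xᵢ − dᵢ)²` subject to the constraints, per axis — then
   remove residual overlaps greedily: each overlapping sibling pair can be
   separated left/right/above/below; the four alternatives are ranked by the
   node movement an exact trial projection would cause and tried in order,
   backtracking when one is infeasible.
4. **Route edges** orthogonally on the visibility structure of the buffered
   obstacle rectangles, minimizing `length + bend_penalty · bends`, with
   ports (consumption/production at the centers of opposite process sides,
   catalysis on a remaining side), checkpoints that bundle reaction-group
   edges to a common divergence point, and nudging that separates collinear
   routes (recursively halving the gap where space is tight).

Output is SBGN-ML (0.2-era schema) and SVG.

## Worked example

No KEGG download is needed: the package ships a seeded synthetic-KGML
generator that emulates the KEGG drawing style (grid-aligned compound
circles, gene rectangles on the reaction edges, map-link boxes) with a
ground-truth manifest.

```python
from kgml2sbgn import generate_kgml, SynthSpec
text, manifest = generate_kgml(
    SynthSpec(n_chains=2, chain_length=4, multi_reaction_pairs=1,
              n_maplinks=1, seed=11))
open("demo.kgml", "w").write(text)
```

```sh
$ kgml2sbgn convert demo.kgml -o demo.sbgn --svg demo.svg --report demo.json
demo.kgml: 29 glyphs, 28 arcs, 0 flagged ambiguities
```

The report (`demo.json`) shows what happened:

```json
{
  "glyphs": 29,
  "arcs": 28,
  "glyph_classes": {"macromolecule": 9, "process": 9, "simple chemical": 9,
                    "submap": 1, "terminal": 1},
  "arc_classes": {"catalysis": 9, "consumption": 7, "equivalence arc": 1,
                  "production": 11},
  "reaction_groups": 1,
  "layout": {"movement_px": 262.713, "accepted_nonoverlap_constraints": 8,
             "unresolved_overlaps": [], "hard_constraint_violations": []},
  "routing": {"straight_fallbacks": [], "corridor_failures": []}
}
```

Reading it: 8 compounds + 1 branch compound became simple chemicals, the 9
catalysed reactions each became a macromolecule/process pair (hence 9
catalysis arcs), the one map link became a submap with one terminal and an
equivalence arc, and the two parallel reactions between one compound pair
were detected as a reaction group (their consumption/production arcs are
bundled through shared checkpoints). The layout moved nodes by 263 px in
total to make room, added 8 non-overlap separations, and satisfied every
hard constraint; routing needed no straight-line fallbacks. `--no-layout`
writes the raw translated state instead — macromolecules still sitting on
their processes — which is useful to see why layout repair is needed.

Library use mirrors the CLI:

```python
from kgml2sbgn import convert_kgml, write_sbgnml, render_svg
outcome = convert_kgml(open("demo.kgml").read())
open("demo.sbgn", "w").write(write_sbgnml(outcome.map))
open("demo.svg", "w").write(render_svg(outcome.map))
```

Tuning knobs (`--tolerance`, `--margin`, `--enzyme-offset`,
`--bend-penalty`, `--nudge-gap`) are documented in `docs/methods.md`.

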