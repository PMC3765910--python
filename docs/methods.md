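# Methods

This note records the model behind each pipeline stage, the tunable
parameters with their defaults and rationale, the numerical choices, and
what the synthetic test bed does and does not establish about real KEGG
maps.

## Translation model

A KEGG metabolic map is treated as a graph of three node kinds — gene
products, compounds, and "another map" boxes — connected by reaction edges
and map-link edges. The SBGN PD translation is one-to-one where possible
(compound → simple chemical, map box → submap, map link → equivalence arc
with a terminal added on the submap border) and node-increasing for
reactions: every catalyst entry of every reaction yields one macromolecule
*and* one process glyph plus a catalysis arc. A catalyst entry that names
several reactions therefore yields several macromolecule copies (no clone
markers are emitted); a reaction drawn twice in KEGG yields two processes,
which is precisely what creates reaction groups. Irreversible reactions get
consumption arcs (substrate → process) and production arcs (process →
product); reversible reactions get production arcs on both sides, which is
how PD expresses reversibility without a marker. KGML group entries become
complex glyphs whose bbox is the member union plus an 8 px margin.

Edge cases: a reaction with no catalyst entry becomes a bare process
(no macromolecule, no catalysis arc); a gene entry catalysing nothing
becomes a standalone macromolecule; relations other than `maplink` are
skipped with a warning rather than guessed at.

Defective KGML is never silently repaired. A reaction without a `type`
attribute is translated as irreversible but its process and arcs are
flagged; participants with unresolvable roles and reactions missing
substrates or products entirely are likewise flagged, and flags survive
through layout, SBGN-ML serialization (a small extension attribute) and SVG
(red stroke).

## Constraint inference and layout

Node placement is a per-axis convex quadratic program over glyph centers
and free guide variables: minimize the squared displacement from desired
positions (the original KGML coordinates, or the derived positions for
added nodes) subject to separation constraints `u + g ≤ v` and `u + g = v`.

**Recognizability.** Per axis, compound and process centers are clustered
by 1-D single linkage: sorted coordinates chain into one group while
consecutive gaps stay within the tolerance (default **4 px**; KEGG curators
align within a few pixels, and grid jitter in real maps is below this).
Groups of two or more become alignment constraints whose guide is a free
variable co-optimized with the nodes, so a whole row can shift to make
room. Consecutive guides and unaligned singletons, sorted by coordinate,
are chained by inequality separations with gap `max(min_group_gap, h₁+h₂)`
(half-extents of the widest members, enlarged sizes; `min_group_gap`
default **20 px**), so the original reading order can never invert.
Reaction-group member processes are excluded from this chain on the group
axis — their order and spacing is already fixed by the group's equality
chain, and a generic order gap would contradict the tighter group spacing.

**Style.** Each enzyme macromolecule is fixed relative to its process by an
alignment on one axis plus an equality separation of **35 px** on the other
(above the process for horizontal flow, left of it for vertical flow; the
offset clears the enlarged node boxes while keeping the catalysis arc
short). Terminals are pinned to their submap border by an equality and held
within the border span by containment inequalities with margin 0 on the
shared side; complex members are held inside with a 2 px margin.
Reaction-group processes share an alignment on the axis perpendicular to
the group and are spaced **25 px** apart by equality separations, with
inequalities keeping the stack strictly between its two compounds.

**Projection solver.** The per-axis QP is solved exactly by block merging:
equalities are eliminated first (union-find with offsets; contradictions
raise with the violated cycle named), then a violated inequality merges the
two rigid blocks it spans, a violated inequality inside a block retracts
the weakest *forward* active constraint on the path between its endpoints
(a path with no forward edge closes a positive-gap cycle, i.e. the system
is infeasible), and an active constraint with a negative Lagrange
multiplier is retracted. At termination the KKT conditions hold, so the
result is the exact minimizer; the test suite checks it against an
independent oracle that enumerates every active subset and solves the KKT
system densely (agreement ≤ 1e-6 px on hundreds of random instances; in
practice ~1e-13).

**Non-overlap.** Nodes are enlarged by `node_margin` (default **10 px**
per side) during layout, which reserves routing space between final boxes.
Overlapping sibling pairs — containment hierarchies exempt parent/child —
are processed in descending overlap area. Each pair has four candidate
separations (left, right, above, below, gaps from the enlarged sizes);
each candidate is evaluated by an exact trial projection and they are tried
in order of the total movement they cause (ties: x before y, first-id-left
before right). An infeasible candidate is discarded (positions reset); if
all four fail the overlap is reported unresolved. Pairs rigidly co-located
by equality chains on *both* axes (an enzyme with its process, consecutive
group processes) are deliberate placements whose enlarged boxes touch by
construction; all four candidates would contradict the hard equalities, so
they are skipped rather than reported. Axes are solved x first, then y.

## Edge routing

Routing works on the interesting-coordinate grid: every buffered obstacle
corner (buffer default **4 px**) and every connection point contributes a
horizontal and a vertical line; an optimal orthogonal path always lies on
this grid, so a Dijkstra over (grid point, heading) states with cost
`length + bend_penalty · bends` (default **20 px** per bend — roughly "a
bend is as bad as 20 px of extra wire") is exactly optimal. 180° turns at a
vertex are disallowed (the route would retrace itself). Maps with at most
40 obstacles are routed on the full grid (provably optimal; this covers
the oracle comparisons); larger maps crop to a region around each
connector, growing it on failure, trading optimality for speed.

Each enzyme/process pair is merged into one expanded obstacle (union bbox
plus buffer) so foreign edges cannot cross the catalysis arc; the pair's
own arcs see the partner's individual box instead. Consumption and
production arcs attach to the midpoints of opposite process sides along the
substrate→product axis; catalysis attaches to a remaining side nearer the
macromolecule; terminals force the edge out through the submap border they
sit on; everything else attaches center-on and is trimmed to the border
after routing. Ports force the first/last heading of the route.

Reaction-group edges are bundled with checkpoints: per group and compound
side, one checkpoint just outside the group's near process, carried by
every arc between that compound and any group process. Legs between
waypoints are solved by a small dynamic program over the heading at each
checkpoint, so a heading change there is charged like any other bend and
the concatenation is optimal for the piecewise problem.

**Nudging.** Collinear overlapping segments of distinct routes (grouped by
axis and cross-coordinate, clustered by interval overlap) receive distinct
perpendicular offsets, ideally a symmetric fan at `nudge_gap` (default
**4 px**) ordered by each route's far endpoint. A bundle's shared corridor
is pinned at offset zero so checkpoints stay on their routes. Candidate
offsets must keep attachment points strictly within the node side they
enter (this is the fan of multiple edges entering one side, bounded by the
node), must not cross buffered obstacle interiors, and must not land on
another already-placed segment; when a cluster cannot be assigned at the
current gap, the whole cluster retries at halved gaps (floor 1 px), and a
corridor failing even then is reported. Because moving a segment stretches
its perpendicular neighbors, nudging iterates to a fixpoint (at most four
passes); junctions between collinear segments with different offsets get a
perpendicular jog so routes stay orthogonal.

## Serialization and rendering

SBGN-ML output follows the plain 0.2-era schema (map/glyph/arc, bbox as
top-left + size, arc geometry as start/next/end points); terminals nest
inside their submap glyph with an `orientation` attribute, complex members
inside their complex. Coordinates print with 6 significant digits, which
makes write → parse → write a byte-identical fixpoint. Ambiguity flags and
the originating KGML ids ride in two extension attributes under a package
namespace. The SVG renderer draws glyphs first and arcs on top (so an
unavoidable node crossing shows the edge), keeps all labels horizontal,
rounds route corners slightly, and strokes flagged elements red.

## Synthetic test bed

The generator emulates the KEGG drawing style: chains of compounds on a
90 px grid in 162 px-spaced columns, gene rectangles (46×17 px) midway
along reaction edges, compound circles upscaled to 20 px for SBGN, optional
side branches, 2–3 parallel reactions on selected compound pairs, and
map-link boxes below chain ends — all with sub-tolerance jitter (default
2 px) so alignment must genuinely be inferred. Its manifest records exact
counts and the expected alignment clusters (computed from the jitter-free
coordinates), giving every stage a ground truth without any download.

What passing on this bed shows: the count law, flag propagation, constraint
satisfaction, overlap removal, routing optimality and nudging behave
correctly on maps with the geometry KEGG uses. What it does not show:
robustness to the full messiness of real KGML (exotic entry types, large
group entries, maps with thousands of nodes, degenerate coordinates); the
parser is deliberately lenient there (warn-and-continue) but those paths
are only lightly exercised. Runtime figures come from maps up to ~330
entries (~490 glyphs), which complete the full pipeline in well under a
minute; behavior at several thousand nodes is untested and the local
routing crop means very large maps get locally rather than globally optimal
routes.

## Known limitations

- No layout compaction: preserved order constraints can leave generous
  whitespace when many nodes must move.
- Edge crossings are reduced only implicitly through routing costs and
  nudge ordering; there is no global crossing minimization.
- Labels are centered and may overlap neighboring elements; PD's fixed
  glyph sizes make this unavoidable for long names.
- Unresolved overlaps (all four alternatives infeasible) and corridors
  where even a 1 px nudge gap fails are reported, not repaired.
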