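"""End-to-end conversion pipeline: parse -> detect ambiguities -> translate
-> infer/build constraints -> layout -> route -> serialize."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import constraints as _constraints
from . import kgml_io, layout as _layout, routing as _routing, sbgn_model, translator


@dataclass
class PipelineConfig:
    tolerance: float = _constraints.DEFAULT_TOLERANCE
    node_margin: float = _layout.DEFAULT_NODE_MARGIN
    enzyme_offset: float = translator.DEFAULT_ENZYME_OFFSET
    group_spacing: float = _constraints.DEFAULT_GROUP_SPACING
    min_group_gap: float = _constraints.DEFAULT_MIN_GROUP_GAP
    bend_penalty: float = _routing.DEFAULT_BEND_PENALTY
    buffer: float = _routing.DEFAULT_BUFFER
    nudge_gap: float = _routing.DEFAULT_NUDGE_GAP
    do_layout: bool = True

    def validate(self) -> None:
        for name in ("node_margin", "enzyme_offset", "group_spacing",
                     "min_group_gap", "bend_penalty", "buffer", "nudge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class ConvertOutcome:
    pathway: kgml_io.KgmlPathway
    result: translator.TranslationResult
    flags: list[kgml_io.AmbiguityFlag]
    layout_result: Optional[_layout.LayoutResult] = None
    routing_report: dict = field(default_factory=dict)

    @property
    def map(self) -> sbgn_model.SbgnMap:
        return self.result.map

    def report(self) -> dict:
        glyph_classes: dict[str, int] = {}
        for g in self.map.glyphs:
            glyph_classes[g.glyph_class.value] = (
                glyph_classes.get(g.glyph_class.value, 0) + 1
            )
        arc_classes: dict[str, int] = {}
        for a in self.map.arcs:
            arc_classes[a.arc_class.value] = arc_classes.get(a.arc_class.value, 0) + 1
        rep = {
            "glyphs": len(self.map.glyphs),
            "arcs": len(self.map.arcs),
            "glyph_classes": dict(sorted(glyph_classes.items())),
            "arc_classes": dict(sorted(arc_classes.items())),
            "ambiguity_flags": [
                {"target": f.target, "reason": f.reason.value} for f in self.flags
            ],
            "reaction_groups": len(self.result.groups),
        }
        if self.layout_result is not None:
            rep["layout"] = {
                "movement_px": round(self.layout_result.movement, 3),
                "accepted_nonoverlap_constraints":
                    self.layout_result.accepted_nonoverlap,
                "unresolved_overlaps": [
                    list(p) for p in self.layout_result.unresolved_overlaps
                ],
                "hard_constraint_violations": self.layout_result.violations,
            }
        if self.routing_report:
            rep["routing"] = {
                "straight_fallbacks": self.routing_report.get("fallbacks", []),
                "corridor_failures": self.routing_report.get("corridor_failures", []),
            }
        return rep


def convert_kgml(
    xml_text: str | bytes, config: Optional[PipelineConfig] = None
) -> ConvertOutcome:
    """Run the full conversion on KGML text.

    With ``config.do_layout`` false only the translation and initial
    placement are performed (the raw translated state, overlaps included) and
    arcs keep straight source->target geometry.
    """
    config = config or PipelineConfig()
    config.validate()
    pathway = kgml_io.parse_kgml(xml_text)
    flags = kgml_io.detect_ambiguities(pathway)
    result = translator.translate_pathway(pathway, flags)
    outcome = ConvertOutcome(pathway=pathway, result=result, flags=flags)
    if not config.do_layout:
        # raw translated state: added macromolecule/process nodes still sit
        # on their KEGG gene positions, overlaps included
        return outcome

    translator.place_initial(
        result, enzyme_offset=config.enzyme_offset,
        group_spacing=config.group_spacing,
    )
    cset = _constraints.build_constraint_set(
        result,
        tolerance=config.tolerance,
        min_group_gap=config.min_group_gap,
        group_spacing=config.group_spacing,
        node_margin=config.node_margin,
    )
    outcome.layout_result = _layout.layout_map(
        result, node_margin=config.node_margin, cset=cset
    )
    outcome.routing_report = _routing.route_all(
        result,
        bend_penalty=config.bend_penalty,
        buffer=config.buffer,
        nudge_gap=config.nudge_gap,
    )
    return outcome
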