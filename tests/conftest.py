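from __future__ import annotations

import pytest

from kgml2sbgn import kgml_io, translator


def kgml_doc(body: str, name: str = "path:test") -> str:
    return f'<?xml version="1.0"?>\n<pathway name="{name}" title="test">\n{body}\n</pathway>\n'


def entry(eid, etype, x, y, w=8, h=8, name=None, reaction=None):
    name = name or f"{etype}:{eid}"
    rattr = f' reaction="{reaction}"' if reaction else ""
    return (
        f'<entry id="{eid}" name="{name}" type="{etype}"{rattr}>'
        f'<graphics name="{name}" x="{x}" y="{y}" width="{w}" height="{h}"/></entry>'
    )


def reaction(rid, sub, prod, rtype="irreversible", name=None):
    name = name or f"rn:{rid}"
    t = f' type="{rtype}"' if rtype else ""
    subs = "".join(f'<substrate id="{s}" name="cpd:{s}"/>' for s in sub)
    prods = "".join(f'<product id="{p}" name="cpd:{p}"/>' for p in prod)
    return f'<reaction id="{rid}" name="{name}"{t}>{subs}{prods}</reaction>'


@pytest.fixture
def simple_irreversible_kgml() -> str:
    """Two compounds left/right, one gene catalyst midway, one irreversible
    reaction."""
    return kgml_doc(
        entry("1", "compound", 40, 200)
        + entry("2", "compound", 160, 200)
        + entry("3", "gene", 100, 200, w=46, h=17, reaction="rn:r1")
        + reaction("r1", ["1"], ["2"])
    )


@pytest.fixture
def simple_reversible_kgml() -> str:
    return kgml_doc(
        entry("1", "compound", 40, 200)
        + entry("2", "compound", 160, 200)
        + entry("3", "gene", 100, 200, w=46, h=17, reaction="rn:r1")
        + reaction("r1", ["1"], ["2"], rtype="reversible")
    )


@pytest.fixture
def maplink_kgml() -> str:
    """A compound linked to another map."""
    return kgml_doc(
        entry("1", "compound", 100, 100)
        + entry("2", "map", 300, 100, w=46, h=17, name="path:map00030")
        + '<relation entry1="1" entry2="2" type="maplink">'
        '<subtype name="compound" value="1"/></relation>'
    )


@pytest.fixture
def multi_reaction_kgml() -> str:
    """Two compounds stacked vertically with two parallel catalysed reactions."""
    return kgml_doc(
        entry("1", "compound", 100, 60)
        + entry("2", "compound", 100, 260)
        + entry("3", "gene", 130, 140, w=46, h=17, reaction="rn:r1")
        + entry("4", "gene", 130, 180, w=46, h=17, reaction="rn:r2")
        + reaction("r1", ["1"], ["2"])
        + reaction("r2", ["1"], ["2"])
    )


def translated(kgml_text: str) -> translator.TranslationResult:
    pathway = kgml_io.parse_kgml(kgml_text)
    flags = kgml_io.detect_ambiguities(pathway)
    result = translator.translate_pathway(pathway, flags)
    return translator.place_initial(result)
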