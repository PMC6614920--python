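"""Curated loop-receptor signature set (synthetic reconstruction).

The published construct sequences appear only in figure panels, so the
signatures shipped here are a synthetic reconstruction: 23-position
sequences built to satisfy every relationship stated for the constructs in
the accompanying characterization -

* 3SUX, 158 and 148 are each one point mutation from 980 (G9:U21 wobble,
  G7A, and U3C respectively);
* 593 is two mutations from 980 (G10:C20 -> A10:U20);
* 4LVV differs from 980 at eight positions and carries the U6/C14/del17
  context, an A10:U20 pair and three G:C pairs in the long-range pairing;
* 980/3SUX/593/148/158 share the C6/U14/C17 context;
* 488.1 has four G:C long-range pairs plus an A:A mismatch at 11:19;
* 894 adds an inserted G6.1 to the 593 background;
* position 7 is a conserved G across the natural set.

They are suitable for exercising the signature, family and consensus
machinery; they are not the figure sequences themselves.
"""

from __future__ import annotations

from .positions import canonical_labels
from .signature import LoopReceptorVariant, parse_variant_name

__all__ = ["curated_variants", "CURATED_SEQUENCES"]


def _residues(seq23: str, **overrides) -> dict[str, str]:
    """Build a residue map from a 23-mer plus label overrides.

    An override of ``None`` deletes the position; fractional labels insert.
    """
    res = dict(zip(canonical_labels(), seq23))
    for label, base in overrides.items():
        label = label.replace("p", "").replace("_", ".")
        if base is None:
            res.pop(label, None)
        else:
            res[label] = base
    return res


# 980 backbone: C6/U14/C17 context, long-range pairing G8:C22 G9:C21
# G10:C20 G11:U19 G12:C18 (four G:C pairs, one wobble at 11:19).
_980 = "AGUAACGGGGGGUUAACCUCCCG"

#: id -> (residue map, source). Stem lengths come from the construct name.
CURATED_SEQUENCES: dict[str, tuple[dict[str, str], str]] = {
    "980": (_residues(_980), "natural"),
    # G9:C21 -> G9:U21 wobble; one mutation from 980.
    "3SUX": (_residues(_980, p21="U"), "natural"),
    # G7A; one mutation from 980.
    "158": (_residues(_980, p7="A"), "natural"),
    # U3C (impairs ligand recognition); one mutation from 980.
    "148": (_residues(_980, p3="C"), "natural"),
    # G10:C20 -> A10:U20; two mutations from 980.
    "593": (_residues(_980, p10="A", p20="U"), "natural"),
    # 593 background plus an extra G between positions 6 and 7.
    "894": (_residues(_980, p10="A", p20="U", p6_1="G"), "natural"),
    # U6/C14/del17 context, A10:U20 and A11:U19, G2A, A16U;
    # eight differences from 980; three G:C long-range pairs.
    "4LVV": (
        _residues(
            _980, p2="A", p6="U", p10="A", p11="A", p14="C", p16="U", p17=None,
            p20="U",
        ),
        "natural",
    ),
    # 4LVV background with G10:C20 restored (four G:C long-range pairs).
    "488": (
        _residues(
            _980, p2="A", p6="U", p11="A", p14="C", p16="U", p17=None,
        ),
        "natural",
    ),
    # U3C variant of 3SUX.
    "3SUX.1": (_residues(_980, p21="U", p3="C"), "artificial"),
    # C6U alone (context change split from C17del).
    "980.1": (_residues(_980, p6="U"), "artificial"),
    # C17del alone.
    "980.2": (_residues(_980, p17=None), "artificial"),
    # G8:C22 -> G8:U22 wobble.
    "980.8": (_residues(_980, p22="U"), "artificial"),
    # G7C (tolerated, unlike G7A).
    "980.10": (_residues(_980, p7="C"), "artificial"),
    # G8:C22 swapped to C8:G22.
    "980.11": (_residues(_980, p8="C", p22="G"), "artificial"),
    # A10:U20 of 4LVV swapped to U10:A20 (pyrimidine in the loop strand).
    "4LVV.1": (
        _residues(
            _980, p2="A", p6="U", p10="U", p11="A", p14="C", p16="U", p17=None,
            p20="A",
        ),
        "artificial",
    ),
    # A11:A19 mismatch on the 4LVV background (three G:C pairs).
    "4LVV.2": (
        _residues(
            _980, p2="A", p6="U", p10="A", p11="A", p14="C", p16="U", p17=None,
            p19="A", p20="U",
        ),
        "artificial",
    ),
    # 4LVV.2 with the 10:20 pair swapped to U10:A20.
    "4LVV.3": (
        _residues(
            _980, p2="A", p6="U", p10="U", p11="A", p14="C", p16="U", p17=None,
            p19="A", p20="A",
        ),
        "artificial",
    ),
    # Four G:C pairs plus the A11:A19 mismatch (tolerated background).
    "488.1": (
        _residues(
            _980, p2="A", p5="C", p6="U", p11="A", p14="C", p16="U", p17=None,
            p19="A",
        ),
        "artificial",
    ),
}


def curated_variants() -> list[LoopReceptorVariant]:
    """The curated signature set as LoopReceptorVariant objects."""
    out = []
    for name, (residues, source) in CURATED_SEQUENCES.items():
        base_id, stem, suffix = parse_variant_name(name)
        out.append(
            LoopReceptorVariant(
                id=name,
                residues=residues,
                base_id=base_id,
                stem_length_bp=stem,
                variant_suffix=suffix,
                source=source,
            )
        )
    return out
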