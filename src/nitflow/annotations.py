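"""Static functional-guild annotation of the reactor's dominant genera.

A packaged literature-derived lookup mapping the genera that dominate
autotrophic nitrogen-removal reactors to their nitrogen-cycle functions.
Unknown genera return an empty set.
"""

from __future__ import annotations

__all__ = ["GUILD_ANNOTATION", "annotate_guilds"]

GUILD_ANNOTATION: dict[str, frozenset[str]] = {
    "Nitrospira": frozenset({
        "aerobic nitrite oxidation (NOB)",
        "complete ammonium oxidation (comammox)",
    }),
    "Candidatus Jettenia": frozenset({"anammox"}),
    "Nitrosomonas": frozenset({"aerobic ammonium oxidation (AOB)"}),
    "SM1A02": frozenset({"anammox", "candidate"}),
    "Groundwater metagenome": frozenset({"anammox", "candidate"}),
    "Denitratisoma": frozenset({"denitrification"}),
    "AKYH767": frozenset({"chemoheterotrophy"}),
    "OLB12": frozenset({"chemoheterotrophy"}),
    "Sideroxydans": frozenset({"iron oxidation", "chemoheterotrophy"}),
    "Bryobacter": frozenset({"chemoheterotrophy"}),
}


def _canonical(genus: str) -> str:
    return genus.replace("_", " ").strip()


def annotate_guilds(genera: list[str]) -> dict[str, frozenset[str]]:
    """Map each genus to its known functional labels (empty if unknown).

    Underscore and space spellings are treated as equivalent
    ("Candidatus_Jettenia" == "Candidatus Jettenia").
    """
    return {g: GUILD_ANNOTATION.get(_canonical(g), frozenset())
            for g in genera}
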