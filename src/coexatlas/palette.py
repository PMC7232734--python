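"""Ordered color palette for module labels.

Modules are named by decreasing size from this fixed list so that labels
are reproducible across runs; ``grey`` is reserved for unassigned genes.
Beyond the palette, labels continue as ``module<k>``.
"""

UNASSIGNED = "grey"

PALETTE: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
    "sienna", "yellowgreen", "skyblue3", "plum", "orangered", "mediumpurple",
    "lightsteelblue", "lightcyan1", "ivory", "floralwhite", "darkseagreen",
    "brown4", "bisque", "darkslateblue", "plum2", "thistle",
)


def module_label(rank: int) -> str:
    """Label for the module of size-rank ``rank`` (0-based)."""
    if rank < len(PALETTE):
        return PALETTE[rank]
    return f"module{rank + 1:03d}"
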