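"""Exception classes shared across the package."""


class PDSetsError(Exception):
    """Base class for all domain errors raised by this package."""


class TreeFormatError(PDSetsError):
    """Malformed Newick input, a missing/non-positive edge length, or a
    duplicate or empty leaf label."""


class NotUltrametricError(PDSetsError):
    """Raised when an operation requires clock-like (ultrametric) branch
    lengths but two root-to-leaf distances differ beyond tolerance.

    Attributes
    ----------
    leaf_a, leaf_b : str
        A witnessing pair of leaves with discordant root distances.
    dist_a, dist_b : float
        Their root-to-leaf path lengths.
    """

    def __init__(self, leaf_a: str, leaf_b: str, dist_a: float, dist_b: float):
        self.leaf_a = leaf_a
        self.leaf_b = leaf_b
        self.dist_a = dist_a
        self.dist_b = dist_b
        super().__init__(
            f"tree is not ultrametric: d(root, {leaf_a}) = {dist_a:g} but "
            f"d(root, {leaf_b}) = {dist_b:g}"
        )


class UnknownLabelError(PDSetsError):
    """A queried leaf label is not present in the tree."""


class InvalidSizeError(PDSetsError):
    """A subset size k lies outside the valid range for the operation."""
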