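"""Exception types raised across the pipeline.

All errors derive from :class:`EndofcError` so callers can catch the
package's failures with a single except clause while still being able to
distinguish a parse problem from, say, an empty atom selection.
"""


class EndofcError(Exception):
    """Base class for all endofc errors."""


class ParseError(EndofcError):
    """A coordinate file could not be parsed in the requested dialect."""


class FormatError(EndofcError):
    """An unknown or unsupported file format was requested."""


class EmptySelectionError(EndofcError):
    """An atom selection resolved to zero atoms."""


class InsufficientAtomsError(EndofcError):
    """Fewer than the minimum number of paired atoms for a rigid fit."""


class NoOverlapError(EndofcError):
    """Two selections share no (seq_id, atom_name) pairs."""


class MissingAtomError(EndofcError):
    """A named atom required by a geometric computation is absent."""


class UnknownElementError(EndofcError):
    """An atom's element has no entry in the radii / solvation table."""


class NoGlycanError(EndofcError):
    """No saccharide residue found within covalent-bond distance of an Asn."""
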