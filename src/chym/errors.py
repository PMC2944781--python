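"""Exception hierarchy.

Every domain error raised by the library derives from :class:`ChymError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class ChymError(Exception):
    """Base class for all library errors."""


class OboParseError(ChymError):
    """Malformed OBO input (e.g. a [Term] stanza without an id line)."""


class CycleError(ChymError):
    """The normalized ontology still contains a directed cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"residual cycle after relation exclusion: {' -> '.join(self.cycle)}")


class UnknownTermError(ChymError, KeyError):
    """A term id does not resolve in the ontology graph."""

    def __init__(self, term_id):
        self.term_id = term_id
        super().__init__(f"unknown term id: {term_id!r}")


class UnknownBranchError(ChymError, ValueError):
    """A branch name outside {structure, role, subatomic, all}."""


class StructureParseError(ChymError):
    """A SMILES or MDL structure string failed to parse."""

    def __init__(self, text, fmt):
        self.text = text
        self.fmt = fmt
        super().__init__(f"could not parse {fmt} structure: {text!r}")


class NoUsableStructureError(ChymError):
    """A compound has no SMILES or MDL record (InChI alone is not used)."""


class PatternError(ChymError):
    """A substructure pattern failed to compile."""

    def __init__(self, pattern, lineno):
        self.pattern = pattern
        self.lineno = lineno
        super().__init__(f"invalid pattern at line {lineno}: {pattern!r}")


class FingerprintComparisonError(ChymError):
    """Fingerprints of different formats or lengths were compared."""


class DegenerateFingerprintError(ChymError):
    """Both fingerprints in a comparison are all-zero (undefined Tanimoto)."""


class DegenerateICError(ChymError):
    """The IC sum over an ancestor union is zero (undefined simGIC)."""


class ScoringError(ChymError):
    """A compound cannot be scored under a metric (names the missing resource)."""


class ScopedTermError(ScoringError):
    """A term does not belong to the requested ontology branch."""

    def __init__(self, term_id, branch):
        self.term_id = term_id
        self.branch = branch
        super().__init__(f"term {term_id!r} is not in the {branch!r} branch")


class DegenerateTrainingError(ChymError):
    """Training requires at least two active compounds (self-exclusion)."""
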