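"""Exception hierarchy for trihelix."""


class TrihelixError(Exception):
    """Base class for all trihelix errors."""


class AlphabetError(TrihelixError):
    """A residue outside the 21-letter alphabet (20 canonical + 'O')."""


class FrameError(TrihelixError):
    """Glycine pattern inconsistent with any single Xaa-Yaa-Gly frame."""


class ConfigError(TrihelixError):
    """Invalid user configuration (ranges, motifs, exclusions)."""


class ParameterError(TrihelixError):
    """Malformed or incomplete scoring-parameter table."""


class FastaError(TrihelixError):
    """Unreadable peptide record in a FASTA or plain-text file."""
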