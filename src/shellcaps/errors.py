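"""Exception hierarchy shared across the pipeline."""


class ShellcapsError(Exception):
    """Base class for all pipeline errors."""


class SequenceError(ShellcapsError, ValueError):
    """Invalid nucleotide input (bad alphabet, bad position, empty sequence)."""


class FormatError(ShellcapsError, ValueError):
    """Malformed input file (ragged alignment, empty FASTA, unparsable table)."""


class ConfigError(ShellcapsError, ValueError):
    """Invalid or infeasible configuration."""


class PipelineError(ShellcapsError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
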