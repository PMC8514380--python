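"""Typed exceptions raised by the tp53sig library.

Every validation failure maps to one of these classes so that callers (and the
analysis drivers) can distinguish bad input from genuine numerical failure.
"""


class Tp53SigError(Exception):
    """Base class for all tp53sig errors."""


class PanelError(Tp53SigError):
    """Malformed gene panel (duplicates, overlap between roles, empty role)."""


class MissingGeneError(Tp53SigError):
    """A scored panel gene is absent from an expression profile or table."""

    def __init__(self, genes, sample_id=None):
        self.genes = list(genes)
        self.sample_id = sample_id
        where = f" in sample {sample_id!r}" if sample_id else ""
        super().__init__(f"missing panel gene(s){where}: {', '.join(self.genes)}")


class InvalidInputError(Tp53SigError):
    """Negative, non-finite or otherwise out-of-domain numeric input."""


class DegenerateProfileError(Tp53SigError):
    """Down-regulated gene sum is zero; the ratio score is undefined."""


class DuplicateSampleError(Tp53SigError):
    """Duplicate sample identifiers in a cohort."""

    def __init__(self, ids):
        self.ids = list(ids)
        super().__init__(f"duplicate sample_id(s): {', '.join(self.ids)}")


class DegenerateLabelsError(Tp53SigError):
    """ROC analysis needs at least one mutant and one wild reference label."""


class AlignmentError(Tp53SigError):
    """Two tables that must share sample_ids do not."""

    def __init__(self, unmatched, message="sample_id mismatch"):
        self.unmatched = sorted(unmatched)
        super().__init__(f"{message}: {', '.join(self.unmatched)}")


class VocabularyError(Tp53SigError):
    """A categorical clinical field holds a level outside its vocabulary."""


class ParseError(Tp53SigError):
    """A TSV/CSV input file violates its schema."""


class ConvergenceError(Tp53SigError):
    """Proportional-hazards fit failed to converge (e.g. complete separation)."""


class DegenerateGroupingError(Tp53SigError):
    """A grouped test was requested with fewer than two usable groups."""


class ConfigError(Tp53SigError):
    """Invalid simulation or pipeline configuration."""
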