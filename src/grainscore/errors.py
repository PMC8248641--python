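"""Exception hierarchy for the analysis pipeline."""


class GrainscoreError(Exception):
    """Base class for all package errors."""


class SchemaError(GrainscoreError):
    """A file is missing required columns or has a malformed layout."""


class ValidationError(GrainscoreError):
    """A value violates a field-level constraint (range, sign, type)."""


class IntegrityError(GrainscoreError):
    """Cross-field or cross-table consistency violated (duplicates,
    unresolvable foreign keys, contradictory flags)."""


class StratificationError(GrainscoreError):
    """Too few whole-grain consumers in a stratum to form tertiles."""


class ScoringError(GrainscoreError):
    """A diet-quality score is undefined for a participant (zero energy)."""


class ConfigurationError(GrainscoreError):
    """A configuration table is inconsistent with the data it is applied to."""


class EstimationError(GrainscoreError):
    """A model fit is impossible (rank deficiency, empty design)."""
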