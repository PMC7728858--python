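"""Exception hierarchy for contract violations along the pipeline."""


class DiliPredError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(DiliPredError, ValueError):
    """A synthetic study design that cannot be generated (e.g. an empty class)."""


class FormatError(DiliPredError, ValueError):
    """A delimited-text input violates the expected layout."""


class EmptyJoinError(DiliPredError, ValueError):
    """Joining labels onto profiles matched nothing."""


class SelectionError(DiliPredError, ValueError):
    """Profile selection asked for more profiles than exist."""


class StratificationError(DiliPredError, ValueError):
    """A stratified split cannot be formed (class absent or too small)."""


class TrainingError(DiliPredError, ValueError):
    """A classifier cannot be trained on the given data."""


class GeneOrderError(DiliPredError, ValueError):
    """Prediction input gene order differs from the training gene order."""


class LeakageError(DiliPredError, ValueError):
    """Train and validation sets overlap (profiles or drugs)."""


class UndefinedMetricError(DiliPredError, ValueError):
    """A metric is undefined for the given input (e.g. AUC with one class)."""


class SignatureError(DiliPredError, ValueError):
    """Signature extraction parameters incompatible with the gene panel."""
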