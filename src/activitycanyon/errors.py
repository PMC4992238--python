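"""Exception types shared across the package."""


class ActivityCanyonError(Exception):
    """Base class for all package-specific errors."""


class InputConsistencyError(ActivityCanyonError, ValueError):
    """Inputs disagree with each other (mismatched universes, ids, lengths)."""


class InsufficientDataError(ActivityCanyonError, ValueError):
    """Not enough usable data points for the requested computation."""


class DegenerateRegionError(ActivityCanyonError, ValueError):
    """A chemical region is empty or has zero dispersion where spread is required."""


class OutOfSupportError(ActivityCanyonError, ValueError):
    """A query range falls below the support of the fitted distribution."""
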