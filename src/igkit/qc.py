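"""Read quality gate applied before any annotation.

Sanger reads are excluded when they are shorter than 50 nt or when their
mean Phred quality over all bases is below 12 (both configurable).  The
aggregate is the mean because per-base thresholds would discard nearly
every Sanger read at the degraded trace ends; the mean used for the
decision is recorded in the result for auditability.  FASTA input has no
quality information: such reads pass the quality criterion but carry a
``no_quality_data`` warning so the downstream comment column can flag
them.
"""

from __future__ import annotations

from igkit.model import QCResult, SangerRead


def check_quality(read: SangerRead, min_phred: float = 12.0, min_len: int = 50) -> QCResult:
    """Gate one read on length, then mean Phred quality.  Total function."""
    length = len(read)
    if length < min_len:
        return QCResult(passed=False, length=length, reason="too_short")
    if read.qualities is None:
        return QCResult(passed=True, length=length, warning="no_quality_data")
    mean_phred = sum(read.qualities) / length
    if mean_phred < min_phred:
        return QCResult(passed=False, length=length, reason="low_quality", mean_phred=mean_phred)
    return QCResult(passed=True, length=length, mean_phred=mean_phred)
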