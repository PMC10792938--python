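"""Reversion scoring of DMRs and transcripts after drug withdrawal.

The methylation reversion score measures what fraction of the
parental-to-resistant methylation shift a DMR has undone by passage 12 of
drug withdrawal (P12): 0 means the region stayed at the resistant level (or
drifted further), 1 means it returned to (or overshot) the parental level,
and scores above 0.5 mean P12 methylation is closer to the parental than to
the resistant level.  DMRs are flagged as reverting when their score exceeds
an empirical quantile of the score distribution (default the 90% quantile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .methylome import DMR


@dataclass
class ReversionParams:
    quantile_cutoff: float = 0.90
    score_floor: float = 1e-9  # ratio guard for the transcript score

    def __post_init__(self):
        if not 0 < self.quantile_cutoff < 1:
            raise ValueError("quantile_cutoff must be in (0, 1)")
        if self.score_floor <= 0:
            raise ValueError("score_floor must be positive")


def methylation_reversion_score(m_P, m_R, m_P12):
    """Fraction of the resistance methylation shift undone at P12, in [0, 1].

    With d1 = m_R - m_P (the resistance shift) and d2 = m_P12 - m_R (the
    withdrawal shift), the score is clamp(-d2 / d1, 0, 1).  The clamp ends
    correspond to the two saturated cases of the piecewise definition: 0 when
    P12 continued in the resistance direction (or did not move), 1 when P12
    reached or overshot the parental level.  Scores > 0.5 hold exactly when
    the P12 level is closer to the parental than to the resistant level.
    Accepts scalars or arrays; m_R == m_P is undefined (not a DMR).
    """
    m_P = np.asarray(m_P, dtype=float)
    m_R = np.asarray(m_R, dtype=float)
    m_P12 = np.asarray(m_P12, dtype=float)
    for v in (m_P, m_R, m_P12):
        if np.any((v < 0) | (v > 1)):
            raise ValueError("methylation levels must lie in [0, 1]")
    d1 = m_R - m_P
    if np.any(d1 == 0):
        raise ValueError(
            "reversion score undefined for m_R == m_P (region was not differential)"
        )
    d2 = m_P12 - m_R
    score = np.clip(-d2 / d1, 0.0, 1.0)
    return float(score) if score.ndim == 0 else score


def classify_reverting_dmrs(
    dmrs: list[DMR], params: ReversionParams | None = None
) -> tuple[list[DMR], float]:
    """Score every DMR, derive the quantile cutoff, and flag reverting DMRs.

    The per-DMR score is the arithmetic mean of per-line scores computed from
    the attached (line, state) mean methylation values; the cutoff is the
    empirical ``quantile_cutoff`` quantile of all scores, and a DMR is
    reverting iff its score is strictly above the cutoff.  Returns the
    (mutated) DMR list and the cutoff value.
    """
    params = params or ReversionParams()
    if not dmrs:
        raise ValueError("no DMRs to classify")
    lines = sorted({ln for d in dmrs for (ln, _) in d.mean_methylation})
    for d in dmrs:
        per_line = []
        for ln in lines:
            for st in ("parental", "resistant", "P12"):
                if (ln, st) not in d.mean_methylation:
                    raise ValueError(
                        f"DMR {d.chrom}:{d.start}-{d.end} is missing the "
                        f"{st!r} mean for line {ln!r}"
                    )
            per_line.append(
                methylation_reversion_score(
                    d.mean_methylation[(ln, "parental")],
                    d.mean_methylation[(ln, "resistant")],
                    d.mean_methylation[(ln, "P12")],
                )
            )
        d.reversion_score = float(np.mean(per_line))
    scores = np.array([d.reversion_score for d in dmrs])
    cutoff = float(np.quantile(scores, params.quantile_cutoff))
    for d in dmrs:
        d.reverting = bool(d.reversion_score > cutoff)
    return dmrs, cutoff


def expression_reversion_score(
    log2fc_P_vs_R: float, log2fc_P12_vs_R: float, score_floor: float = 1e-9
) -> float:
    """Reversion score for a transcript from two log2 fold changes vs resistant.

    Zero if the parental-vs-resistant change is small (|log2FC| < 1) or if the
    two fold changes disagree in sign; otherwise the ratio of the larger to
    the smaller absolute fold change (>= 1), so a score near 1 means the P12
    expression change mirrors the parental one.  The denominator is floored
    at ``score_floor`` to guard the log2FC(P12, R) == 0 edge.
    """
    l1, l2 = float(log2fc_P_vs_R), float(log2fc_P12_vs_R)
    if not (np.isfinite(l1) and np.isfinite(l2)):
        raise ValueError("log2 fold changes must be finite")
    if -1 < l1 < 1:
        return 0.0
    if l1 * l2 < 0:
        return 0.0
    a, b = abs(l1), abs(l2)
    return max(a, b) / max(min(a, b), score_floor)


def p5_intermediacy(dmrs: list[DMR]) -> tuple[float, list[bool]]:
    """Fraction of DMRs whose P5 methylation lies between resistant and P12.

    Betweenness is inclusive and must hold in every line with attached means.
    Returns the aggregate fraction and the per-DMR booleans.
    """
    if not dmrs:
        return 0.0, []
    flags = []
    for d in dmrs:
        lines = sorted({ln for (ln, _) in d.mean_methylation})
        ok = True
        for ln in lines:
            try:
                m_r = d.mean_methylation[(ln, "resistant")]
                m_p5 = d.mean_methylation[(ln, "P5")]
                m_p12 = d.mean_methylation[(ln, "P12")]
            except KeyError as exc:
                raise ValueError(
                    f"DMR {d.chrom}:{d.start}-{d.end} lacks state means "
                    f"for line {ln!r}"
                ) from exc
            lo, hi = min(m_r, m_p12), max(m_r, m_p12)
            if not (lo <= m_p5 <= hi):
                ok = False
                break
        flags.append(ok)
    return float(np.mean(flags)), flags
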