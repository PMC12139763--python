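"""Intron-internal domain coordinates.

A DomainMap describes one intron in intron-relative 0-based half-open
coordinates: the six secondary-structure domains D1-D6, the catalytic triad
at the D5 stem start, the branch-point adenosine bulged in D6, the EBS loci
in D1 loops, and the lambda/epsilon' region used for subtype classification.
Maps come either from the synthetic generator (exact) or from structural
inference on a detected candidate (approximate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import Interval


@dataclass
class DomainMap:
    d1: Interval | None = None
    d2: Interval | None = None
    d3: Interval | None = None
    d4: Interval | None = None
    d5: Interval | None = None
    d6: Interval | None = None
    triad: int | None = None  # position of the AGC/CGC triad (== d5.start)
    branch_a: int | None = None  # bulged adenosine position in D6
    ebs1: Interval | None = None
    ebs2: Interval | None = None
    d1_loops: list[Interval] = field(default_factory=list)
    lambda_eps: Interval | None = None
    d5_loop: Interval | None = None
    orf: Interval | None = None  # IEP/HEG ORF within D4, when present
    #: planted pairing loci, name -> (interval, partner interval); filled by
    #: the generator as ground truth, never by inference
    interactions: dict[str, tuple[Interval, Interval]] = field(default_factory=dict)

    def anchor(self, name: str, seq_len: int) -> int | None:
        """Resolve a named anchor to an intron-relative base position."""
        table: dict[str, int | None] = {
            "five_prime_start": 0,
            "intron_end": seq_len,
            "d1_start": self.d1.start if self.d1 else None,
            "d1_end": self.d1.end if self.d1 else None,
            "d2_start": self.d2.start if self.d2 else None,
            "d2_end": self.d2.end if self.d2 else None,
            "d3_start": self.d3.start if self.d3 else None,
            "d3_end": self.d3.end if self.d3 else None,
            "d4_start": self.d4.start if self.d4 else None,
            "d5_start": self.d5.start if self.d5 else None,
            "d6_start": self.d6.start if self.d6 else None,
            "d6_end": self.d6.end if self.d6 else None,
            "lambda_eps_start": self.lambda_eps.start if self.lambda_eps else None,
            "lambda_eps_end": self.lambda_eps.end if self.lambda_eps else None,
            "d5_loop_start": self.d5_loop.start if self.d5_loop else None,
            "d5_loop_end": self.d5_loop.end if self.d5_loop else None,
        }
        if name not in table:
            raise KeyError(f"unknown anchor {name!r}")
        return table[name]
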