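"""Communication accounting for protocol executions.

Every message that a simulated party would put on the wire is counted here,
at the granularity of one backend element per message.  ``message_size_bits``
defaults to 32 regardless of the actual backend width, matching the common
convention of reporting cost in 32-bit words.
"""

from __future__ import annotations

from collections import defaultdict


class CommLedger:
    """Message/bit counters with a per-protocol breakdown and an opening log.

    The opening log records every value that is reconstructed in the clear
    during a run (Beaver d/e openings, the revealed inversion trace, the
    final model) and is the hook used to check that nothing else ever is.
    """

    def __init__(self, message_size_bits: int = 32):
        self.message_size_bits = int(message_size_bits)
        self.messages = 0
        self.breakdown: dict[str, int] = defaultdict(int)
        self.openings: list[str] = []

    @property
    def bits(self) -> int:
        return self.messages * self.message_size_bits

    def record(self, protocol: str, n_messages: int) -> None:
        if n_messages < 0:
            raise ValueError("message count must be >= 0")
        self.messages += int(n_messages)
        self.breakdown[protocol] += int(n_messages)

    def note_opening(self, kind: str) -> None:
        self.openings.append(kind)

    def snapshot(self) -> dict:
        """Flat key-value report (serializable)."""
        out = {
            "messages": self.messages,
            "bits": self.bits,
            "message_size_bits": self.message_size_bits,
        }
        for name, count in sorted(self.breakdown.items()):
            out[f"messages[{name}]"] = count
        return out

    def reset(self) -> None:
        self.messages = 0
        self.breakdown.clear()
        self.openings.clear()

    def __repr__(self):
        return f"CommLedger(messages={self.messages}, bits={self.bits})"
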