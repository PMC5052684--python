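"""Signed Jaccard similarity between signatures.

Shows the three analytic anchors of the index (1 for identical, -1 for
direction-reversed, 0 for unrelated signatures) and a ranked query
against a small library.
"""

from geosig.similarity import GeneSetPair, query, signed_jaccard

sig = GeneSetPair(up=frozenset(f"g{i}" for i in range(1, 11)),
                  down=frozenset(f"g{i}" for i in range(11, 21)))
print("self similarity:      ", signed_jaccard(sig, sig))
print("direction-reversed:   ", signed_jaccard(sig, sig.reversed()))
other = GeneSetPair(up=frozenset({"h1", "h2"}), down=frozenset({"h3", "h4"}))
print("no shared genes:      ", signed_jaccard(sig, other))

partial = GeneSetPair(up=frozenset({"g1", "g2", "x1"}),
                      down=frozenset({"g11", "x2"}))
library = [("exact copy", sig), ("reversed", sig.reversed()),
           ("partial overlap", partial), ("unrelated", other)]
print("\nquery ranking (signed Jaccard, best match first):")
for name, score in query(sig, library):
    print(f"  {name:16s} {score:+.3f}")
print("positive scores mean concordant up/down overlap; negative scores "
      "mean the candidate moves the same genes in the opposite direction")
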