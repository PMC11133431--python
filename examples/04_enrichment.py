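"""Gene-set overrepresentation of a selected feature list.

Writes a small GMT collection, then tests an interest list (imagine the
positive-BR genes of a PLS component) against it with the
hypergeometric upper tail and BH-FDR, reporting the top sets.
"""

import tempfile
from pathlib import Path

from parcelcorr import overrepresentation_test, read_gmt, top_results

universe = [f"gene{i:03d}" for i in range(60)]
gmt_text = (
    "synaptic_signaling\tdemo\t" + "\t".join(universe[:12]) + "\n"
    "lipid_metabolism\tdemo\t" + "\t".join(universe[12:30]) + "\n"
    "immune_response\tdemo\t" + "\t".join(universe[30:45]) + "\n"
)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "sets.gmt"
    path.write_text(gmt_text)
    collection = read_gmt(path, universe=universe)

# an interest list concentrated in the first set
interest = universe[:8] + [universe[40], universe[50]]
results = overrepresentation_test(interest, collection)

print(f"{'set':<20s} {'overlap':>7s} {'expected':>9s} {'ratio':>6s} "
      f"{'p':>9s} {'q':>9s}")
for r in top_results(results, 10):
    print(f"{r.set_name:<20s} {r.overlap:>7d} {r.expected:>9.2f} "
          f"{r.enrichment_ratio:>6.2f} {r.p:>9.3g} {r.q:>9.3g}")
print("\np is the chance of drawing at least this overlap when sampling "
      "the interest list from the universe; q adjusts across sets")
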