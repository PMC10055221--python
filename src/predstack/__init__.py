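"""Stacking and evaluation of per-residue amino-acid predictor panels.

Tools to read and write 20-way per-residue probability tables, simulate
correlated predictor panels, train a fully-connected stacking network on
top of four base predictors, and evaluate all models (per-protein accuracy,
class accuracy, inter-model correlation, agreement taxonomy, and
confidence-vs-RSA histograms). A small Shrake-Rupley implementation
provides relative solvent accessibility from PDB coordinates.
"""

from predstack.alphabet import CANONICAL_AA, AA_TO_INDEX

__version__ = "0.1.0"

__all__ = ["CANONICAL_AA", "AA_TO_INDEX", "__version__"]
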