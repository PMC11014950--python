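>apoL_synthetic SYNTHETIC stand-in for the horse spleen apoferritin L-chain subunit, reconstructed from public sequence knowledge; used for sequence-level hydrogen bookkeeping when the crystal structure is unavailable
SSQIRQNYSTEVEAAVNRLVNLYLRASYTYLSLGFYFDRDDVALEGVCHFFRELAEEKRE
GAERLLKMQNQRGGRALFQDLQKPSQDEWGTTLDAMKAAIVLEKSLNQALLDLHALGSAQ
ADPHLCDFLESHFLDEEVKLIKKMGDHLTNIQRLVGSQAGLGEYLFERLTLKHD
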