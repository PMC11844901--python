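# Small dictionary of cell-line / cell-type names for the stub recognizer.
CD8+ T cell
CD8+ T cells
CD4+ T cell
CD4+ T cells
T cell
T cells
B cell
B cells
natural killer cell
NK cells
dendritic cell
dendritic cells
macrophage
macrophages
neutrophil
neutrophils
monocyte
monocytes
HeLa
HEK293
Jurkat
THP-1
RAW 264.7
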