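# Local structure cache

Deposited coordinate files are resolved against this directory — the tools
never download anything implicitly. To run the analyses of the PD-L1
complexes (atezolizumab 5X8L, durvalumab 5X8M, PD-1 receptor 4ZQK, PD-L2
paralog 3BOV), populate the cache on a machine with network access:

    interfab fetch --accession 5X8L --accession 5X8M --accession 4ZQK --accession 3BOV

Files are stored as `<accession lowercase>.cif` (`.pdb` also recognized).
The coordinate files themselves are not redistributed with this repository.
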