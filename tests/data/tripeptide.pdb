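CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1                      
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N  
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C  
ATOM      3  C   ALA A   1       2.005   1.424   0.000  1.00  0.00           C  
ATOM      4  O   ALA A   1       1.529   2.274  -0.749  1.00  0.00           O  
ATOM      5  CB  ALA A   1       1.968  -0.721  -1.249  1.00  0.00           C  
ATOM      6  N   GLY A   2       3.002   1.678   0.840  1.00  0.00           N  
ATOM      7  CA  GLY A   2       3.608   3.001   0.932  1.00  0.00           C  
ATOM      8  C   GLY A   2       5.124   2.900   1.063  1.00  0.00           C  
ATOM      9  O   GLY A   2       5.631   2.090   1.836  1.00  0.00           O  
ATOM     10  N   SER A   3       5.843   3.723   0.306  1.00  0.00           N  
ATOM     11  CA  SER A   3       7.301   3.720   0.342  1.00  0.00           C  
ATOM     12  C   SER A   3       7.850   5.142   0.300  1.00  0.00           C  
ATOM     13  O   SER A   3       7.396   5.964  -0.492  1.00  0.00           O  
ATOM     14  CB  SER A   3       7.839   2.950  -0.864  1.00  0.00           C  
ATOM     15  OG  SER A   3       7.360   1.606  -0.824  1.00  0.00           O  
ATOM     16  HG  SER A   3       7.722   1.156  -1.600  1.00  0.00           H  
TER      17      SER A   3                                                      
HETATM   18  O   HOH W 101       8.000   3.000   2.000  1.00  0.00           O  
END                                                                             
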