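     Wiberg bond index matrix in the NAO basis:

         Atom    1       2       3
         ---- ------  ------  ------
      1.  P  0.0000  0.8000  0.1500
      2.  O  0.8000  0.0000  0.0500
      3.  O  0.1500  0.0500  0.0000
      4.  O  0.0500  0.6000  0.1000
      5.  H  0.0200  0.0100  0.7000

         Atom    4       5
         ---- ------  ------
      1.  P  0.0500  0.0200
      2.  O  0.6000  0.0100
      3.  O  0.1000  0.7000
      4.  O  0.0000  0.3000
      5.  H  0.3000  0.0000
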