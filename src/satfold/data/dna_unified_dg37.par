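## RNAfold parameter file v2.0

/* DNA nearest-neighbor free energies at 37 C (dekacal/mol).
   Watson-Crick stack terms from the published unified DNA duplex set;
   loop penalties anchored at short-loop values and extended by
   Jacobson-Stockmayer extrapolation. G.T wobble entries are INF
   (disallowed) in this set; supply a file with finite G.T energies
   to enable wobble pairing. */

# stack
/*  CG    GC    GT    TG    AT    TA    NN */
   -217  -184   INF   INF  -128  -145   INF    /* CG */
   -184  -224   INF   INF  -144  -130   INF    /* GC */
    INF   INF   INF   INF   INF   INF   INF    /* GT */
    INF   INF   INF   INF   INF   INF   INF    /* TG */
   -128  -144   INF   INF   -88  -100   INF    /* AT */
   -145  -130   INF   INF  -100   -58   INF    /* TA */
    INF   INF   INF   INF   INF   INF   INF    /* NN */

# mismatch_hairpin
      0     0     0     0     0    /* CG,N */
      0   -40   -40   -40   -40    /* CG,A */
      0   -40   -40   -40   -40    /* CG,C */
      0   -40   -40   -40   -40    /* CG,G */
      0   -40   -40   -40   -40    /* CG,T */
      0     0     0     0     0    /* GC,N */
      0   -40   -40   -40   -40    /* GC,A */
      0   -40   -40   -40   -40    /* GC,C */
      0   -40   -40   -40   -40    /* GC,G */
      0   -40   -40   -40   -40    /* GC,T */
      0     0     0     0     0    /* GT,N */
      0     0     0     0     0    /* GT,A */
      0     0     0     0     0    /* GT,C */
      0     0     0     0     0    /* GT,G */
      0     0     0     0     0    /* GT,T */
      0     0     0     0     0    /* TG,N */
      0     0     0     0     0    /* TG,A */
      0     0     0     0     0    /* TG,C */
      0     0     0     0     0    /* TG,G */
      0     0     0     0     0    /* TG,T */
      0     0     0     0     0    /* AT,N */
      0   -20   -20   -20   -20    /* AT,A */
      0   -20   -20   -20   -20    /* AT,C */
      0   -20   -20   -20   -20    /* AT,G */
      0   -20   -20   -20   -20    /* AT,T */
      0     0     0     0     0    /* TA,N */
      0   -20   -20   -20   -20    /* TA,A */
      0   -20   -20   -20   -20    /* TA,C */
      0   -20   -20   -20   -20    /* TA,G */
      0   -20   -20   -20   -20    /* TA,T */
      0     0     0     0     0    /* NN,N */
      0     0     0     0     0    /* NN,A */
      0     0     0     0     0    /* NN,C */
      0     0     0     0     0    /* NN,G */
      0     0     0     0     0    /* NN,T */

# dangle5
/*   N     A     C     G     T */
      0   -30   -30   -30   -30    /* CG */
      0   -30   -30   -30   -30    /* GC */
      0     0     0     0     0    /* GT */
      0     0     0     0     0    /* TG */
      0   -10   -10   -10   -10    /* AT */
      0   -10   -10   -10   -10    /* TA */
      0     0     0     0     0    /* NN */

# dangle3
/*   N     A     C     G     T */
      0   -30   -30   -30   -30    /* CG */
      0   -30   -30   -30   -30    /* GC */
      0     0     0     0     0    /* GT */
      0     0     0     0     0    /* TG */
      0   -10   -10   -10   -10    /* AT */
      0   -10   -10   -10   -10    /* TA */
      0     0     0     0     0    /* NN */

# hairpin
    INF   INF   INF   350   381   405   425   441   456   468
    480   490   500   508   516   524   531   537   543   549
    555   560   565   570   574   579   583   587   591   595
    598

# bulge
    INF   360   310   354   385   409   428   445   460   472
    484   494   503   512   520   527   534   541   547   553
    558   564   569   573   578   582   587   591   595   598
    602

# internal
    INF   INF   300   330   360   384   404   420   435   447
    459   469   478   487   495   503   510   516   522   528
    534   539   544   549   553   558   562   566   570   574
    577

# ML_params
/* unpaired  dH  closing  dH  branch  dH */
     10       0     340       0      40       0

# NINIO
     50       0     300

# Misc
/* DuplexInit dH TerminalAT dH */
    100       0       5       0

# gquad
/* stack coefficient a, linker coefficient b */
  -1800    1200

#END
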