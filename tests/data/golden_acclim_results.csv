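site,taxon,n,eligible,observed_median,p,n_resamples,seed
Kahekili,Montipora capitata,15,True,0,0.97555,20000,979854011
Kahekili,Montipora patula,10,True,0,0.99805,20000,1254829296
Kahekili,Pocillopora spp,1,False,-1,,20000,1322004881
Kahekili,Porites lobata,19,True,0,0.98785,20000,493844171
Molokini,Montipora capitata,16,True,0,0.9733,20000,1445204311
Molokini,Montipora patula,15,True,0,0.9741,20000,1484141838
Molokini,Pocillopora spp,2,False,-1.5,,20000,1498234170
Molokini,Porites lobata,23,True,0,0.73665,20000,1681718560
Olowalu,Montipora capitata,12,True,0,0.94785,20000,833865025
Olowalu,Montipora patula,9,False,0,,20000,1026449863
Olowalu,Pocillopora spp,3,False,0,,20000,467142275
Olowalu,Porites lobata,19,True,0,0.98665,20000,1744267716
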