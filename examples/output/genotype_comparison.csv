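measurement,group,reference,n_group,n_reference,p_location,F,p_variance,p_location_adj,stars,variance_star
geneA,mutant,wt,10,10,0.03882717836705775,3.5326732673267345,0.07397329386206071,0.058240767550586624,ns,False
geneB,mutant,wt,10,10,0.0006419339141370896,3.5667938931297742,0.07192159080014413,0.0019258017424112687,**,False
geneC,mutant,wt,10,10,0.49384554079535325,3.2885572139303494,0.09089967688920039,0.49384554079535325,ns,False
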