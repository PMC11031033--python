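study_id,product,strategy_name,delta_e_mean,delta_e_sd,n
vladislavic2022,Colgate Max Expert White,HPD,3.8,,20
kim2020,Toothwhole white,HPD,3.2,,15
kim2020,Vussen 7,HPD,4.26,,15
kim2020,Vussen 28,HPD,4.26,,17
meireles2021a,Close Up White Now,BCD,1.4,,25
meireles2021a,Colgate Maxima Protecao Anticaries,CD,1.4,,25
meireles2021a,Whiteness Perfect 10%,CP10,9.9,,25
meireles2021b,Polanight 10%,CP10,11.4,,20
martini2021,Opalescence PF 10%,CP10,8.5,,46
lopezdarriba2017,Vivastyle Vivadent,CP10,5.77,,25
meireles2009,Whiteness Perfect 10%,CP10,4.3,,46
meireles2010,Whiteness Perfect 10%,CP10,4.0,,46
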