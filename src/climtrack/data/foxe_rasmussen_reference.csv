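common_name,code,sti_degc,occ_early_pct,occ_late_pct,pct_change_printed
Red Knot,REKN,-1.3,0.0,1.6,Inf
Ruddy Turnstone,RUTU,-0.2,7.8,12.5,60
Baird's Sandpiper,BASA,1.2,6.2,0.0,-100
Black-bellied Plover,BBPL,1.2,10.9,7.8,-29
Buff-breasted Sandpiper,BBSA,1.5,1.6,0.0,-100
White-rumped Sandpiper,WRSA,1.6,43.8,46.9,7
Red Phalarope,REPH,2.2,64.1,50.0,-22
Pectoral Sandpiper,PESA,3.3,23.4,20.3,-13
Dunlin,DUNL,3.8,9.4,20.3,117
American Golden Plover,AMGP,5.0,6.3,18.8,200
Semipalmated Sandpiper,SESA,5.1,6.3,25.0,300
Stilt Sandpiper,STSA,5.3,0.0,6.3,Inf
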