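region,scenario,term,mean,se,n,units
global,ssp126,total,227,90,61425,mmol C m-2 yr-1
NH,ssp126,total,88,16,6729,mmol C m-2 yr-1
NI,ssp126,total,336,51,4814,mmol C m-2 yr-1
LL,ssp126,total,1013,522,24070,mmol C m-2 yr-1
SI,ssp126,total,276,148,8566,mmol C m-2 yr-1
SO,ssp126,total,43,25,17246,mmol C m-2 yr-1
global,ssp245,total,311,93,61425,mmol C m-2 yr-1
NH,ssp245,total,103,16,6729,mmol C m-2 yr-1
NI,ssp245,total,409,52,4814,mmol C m-2 yr-1
LL,ssp245,total,1386,548,24070,mmol C m-2 yr-1
SI,ssp245,total,409,153,8566,mmol C m-2 yr-1
SO,ssp245,total,77,26,17246,mmol C m-2 yr-1
global,ssp370,total,371,97,61425,mmol C m-2 yr-1
NH,ssp370,total,106,16,6729,mmol C m-2 yr-1
NI,ssp370,total,430,53,4814,mmol C m-2 yr-1
LL,ssp370,total,1648,574,24070,mmol C m-2 yr-1
SI,ssp370,total,535,159,8566,mmol C m-2 yr-1
SO,ssp370,total,114,27,17246,mmol C m-2 yr-1
global,ssp585,total,520,102,61425,mmol C m-2 yr-1
NH,ssp585,total,180,17,6729,mmol C m-2 yr-1
NI,ssp585,total,608,55,4814,mmol C m-2 yr-1
LL,ssp585,total,2242,609,24070,mmol C m-2 yr-1
SI,ssp585,total,705,168,8566,mmol C m-2 yr-1
SO,ssp585,total,154,28,17246,mmol C m-2 yr-1
global,ssp126,doc,2.0,36,61425,mmol C m-2 yr-1
NH,ssp126,doc,0.31,12,6729,mmol C m-2 yr-1
NI,ssp126,doc,1.0,23,4814,mmol C m-2 yr-1
LL,ssp126,doc,2.5,75,24070,mmol C m-2 yr-1
SI,ssp126,doc,0.98,76,8566,mmol C m-2 yr-1
SO,ssp126,doc,34,22,17246,mmol C m-2 yr-1
global,ssp245,doc,2.5,36,61425,mmol C m-2 yr-1
NH,ssp245,doc,0.28,12,6729,mmol C m-2 yr-1
NI,ssp245,doc,1.0,23,4814,mmol C m-2 yr-1
LL,ssp245,doc,3.0,75,24070,mmol C m-2 yr-1
SI,ssp245,doc,1.7,74,8566,mmol C m-2 yr-1
SO,ssp245,doc,58,22,17246,mmol C m-2 yr-1
global,ssp370,doc,3.0,35,61425,mmol C m-2 yr-1
NH,ssp370,doc,0.27,12,6729,mmol C m-2 yr-1
NI,ssp370,doc,1.1,23,4814,mmol C m-2 yr-1
LL,ssp370,doc,3.3,74,24070,mmol C m-2 yr-1
SI,ssp370,doc,2.5,72,8566,mmol C m-2 yr-1
SO,ssp370,doc,84,23,17246,mmol C m-2 yr-1
global,ssp585,doc,3.9,35,61425,mmol C m-2 yr-1
NH,ssp585,doc,0.29,11,6729,mmol C m-2 yr-1
NI,ssp585,doc,1.4,23,4814,mmol C m-2 yr-1
LL,ssp585,doc,4.6,74,24070,mmol C m-2 yr-1
SI,ssp585,doc,3.3,70,8566,mmol C m-2 yr-1
SO,ssp585,doc,109,22,17246,mmol C m-2 yr-1
global,ssp126,temp,225,78,61425,mmol C m-2 yr-1
NH,ssp126,temp,88,10,6729,mmol C m-2 yr-1
NI,ssp126,temp,335,44,4814,mmol C m-2 yr-1
LL,ssp126,temp,1010,513,24070,mmol C m-2 yr-1
SI,ssp126,temp,275,122,8566,mmol C m-2 yr-1
SO,ssp126,temp,7.7,3.6,17246,mmol C m-2 yr-1
global,ssp245,temp,308,82,61425,mmol C m-2 yr-1
NH,ssp245,temp,103,10,6729,mmol C m-2 yr-1
NI,ssp245,temp,407,45,4814,mmol C m-2 yr-1
LL,ssp245,temp,1382,538,24070,mmol C m-2 yr-1
SI,ssp245,temp,407,129,8566,mmol C m-2 yr-1
SO,ssp245,temp,14,3.8,17246,mmol C m-2 yr-1
global,ssp370,temp,368,86,61425,mmol C m-2 yr-1
NH,ssp370,temp,106,11,6729,mmol C m-2 yr-1
NI,ssp370,temp,428,46,4814,mmol C m-2 yr-1
LL,ssp370,temp,1643,564,24070,mmol C m-2 yr-1
SI,ssp370,temp,532,136,8566,mmol C m-2 yr-1
SO,ssp370,temp,20,4.2,17246,mmol C m-2 yr-1
global,ssp585,temp,515,92,61425,mmol C m-2 yr-1
NH,ssp585,temp,179,12,6729,mmol C m-2 yr-1
NI,ssp585,temp,606,47,4814,mmol C m-2 yr-1
LL,ssp585,temp,2235,600,24070,mmol C m-2 yr-1
SI,ssp585,temp,701,147,8566,mmol C m-2 yr-1
SO,ssp585,temp,28,4.7,17246,mmol C m-2 yr-1
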