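class,reservoir,avg,std,min,max
FOR,AGB,12.06,0.12,,
SF,AGB,6.771,1.135,,
GF,AGB,3.468,2.018,,
RAG,AGB,6.010,1.194,,
IRR,AGB,7.428,2.348,,
PAST,AGB,1.315,0.929,,
RAG_PAST,AGB,3.663,1.062,,
FOR,BGB,8.638,1.633,,
SF,BGB,16.27,6.474,,
GF,BGB,8.109,4.849,,
RAG,BGB,4.207,0.836,,
IRR,BGB,3.343,1.057,,
PAST,BGB,2.622,1.285,,
RAG_PAST,BGB,3.414,1.060,,
FOR,SCS100,82.50,43.60,,
CDO,SCS100,70.30,41.60,,
RAG,SCS100,57.40,33.30,,
IRR,SCS100,78.10,25.50,,
PAST,SCS100,51.70,25.50,,
RAG_PAST,SCS100,62.40,28.10,,
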