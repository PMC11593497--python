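Type of Cost,Type of Resources,Units,Monetary Values (USD),Sources of Information
Structure,IMT device,1 unit,1200,Market price
Structure,Treadmill,1 unit,1150,Market price
Structure,Resistance exercise station,2 units,1132,Market price
Structure,Oxygen supplier device,2 units,960,Market price
Rehabilitation team salaries,"Physicians, physical therapists, nurses, and administrative employment",Per month,2347,Health Secretary of Distrito Federal
Supplies,"Cleaners, nose catheter, individual protective equipment",200 units,1345,SIGTAP
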